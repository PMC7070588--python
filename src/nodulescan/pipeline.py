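"""End-to-end processing: simulate -> gate -> indices -> maps -> fuse -> score.

:func:`run_pipeline` drives the whole chain from a :class:`RunConfig` and
returns every intermediate product; with an output directory set it also
writes CSV tables, mask matrices and rendered PNG maps.  Identical config
and seed reproduce every numeric output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .acoustics import PulseModel, ScanGrid, simulate_scan
from .evaluation import ConfusionSummary, LocalizationReport, confusion, localize
from .grid import GridGeometry
from .indices import DEFAULT_WINDOW_LENGTH, index_table, select_reference
from .mapping import BinaryMap, IndexMap, binarize, fuse, map_from_table, oversample
from .phantom import (GroundTruthMask, PhantomSpec, SCENARIO_SCAN_AREAS,
                      builtin_scenario, rasterize_truth)

__all__ = ["RunConfig", "PipelineResult", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


@dataclass
class RunConfig:
    """Configuration of one full detection run."""

    phantom: str = "agar_fig5"          # builtin scenario name or YAML file path
    scan_area: tuple[float, float] | None = None  # (width_x, width_y) mm
    pitch: float = 2.0                  # mm
    oversample_factor: int = 6
    interpolation: str = "bilinear"
    binarization: str = "kmeans"
    pulse: PulseModel = field(default_factory=PulseModel)
    noise_snr_db: float = 30.0
    seed: int = 0
    reference_points: list[tuple[int, int]] | None = None
    window_length: float = DEFAULT_WINDOW_LENGTH
    fusion: tuple[str, ...] = ("and", "or")
    output_dir: str | None = None

    def resolve_phantom(self) -> PhantomSpec:
        if isinstance(self.phantom, PhantomSpec):
            return self.phantom
        if isinstance(self.phantom, str) and Path(self.phantom).expanduser().is_file():
            return PhantomSpec.from_yaml(Path(self.phantom).expanduser())
        return builtin_scenario(self.phantom)

    def resolve_scan_area(self) -> tuple[float, float]:
        if self.scan_area is not None:
            return tuple(self.scan_area)  # type: ignore[return-value]
        if isinstance(self.phantom, str) and self.phantom in SCENARIO_SCAN_AREAS:
            return SCENARIO_SCAN_AREAS[self.phantom]
        spec = self.resolve_phantom()
        return (spec.length, spec.width)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "pulse" in doc and isinstance(doc["pulse"], dict):
            doc["pulse"] = PulseModel(**doc["pulse"])
        if "fusion" in doc:
            doc["fusion"] = tuple(doc["fusion"])
        return cls(**doc)

    def digest(self) -> str:
        doc = asdict(self)
        doc["phantom"] = (self.phantom.to_yaml() if isinstance(self.phantom, PhantomSpec)
                          else self.phantom)
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one run produces."""

    config: RunConfig
    phantom: PhantomSpec
    grid: ScanGrid
    table: pd.DataFrame
    index_maps: dict[str, IndexMap]           # native-pitch cia / cis
    oversampled_maps: dict[str, IndexMap]
    binary_maps: dict[str, BinaryMap]         # cia, cis, and, or
    truth: GroundTruthMask
    confusions: dict[str, ConfusionSummary]
    localizations: dict[str, LocalizationReport]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full detection chain described by ``config``."""
    phantom = _stage("phantom")(config.resolve_phantom)()
    width_x, width_y = config.resolve_scan_area()
    geometry = GridGeometry.from_extent(width_x, width_y, config.pitch)
    logger.info("pipeline: phantom=%s grid=%dx%d (%d points) seed=%d",
                phantom.name, geometry.n_x, geometry.n_y, geometry.n_points,
                config.seed)

    grid = _stage("simulate")(simulate_scan)(
        phantom, geometry, pulse=config.pulse, noise_snr_db=config.noise_snr_db,
        seed=config.seed)

    reference = _stage("reference")(select_reference)(
        grid, config.reference_points, config.window_length)
    table = _stage("indices")(index_table)(
        grid, reference=reference, window_length=config.window_length)
    logger.info("indices: %d points gated, %d unclassifiable",
                len(table), int((~table["classifiable"]).sum()))

    index_maps = {kind: map_from_table(table, geometry, kind) for kind in ("cia", "cis")}
    oversampled = {kind: _stage("oversample")(oversample)(
        imap, config.oversample_factor, config.interpolation)
        for kind, imap in index_maps.items()}
    binary_maps = {kind: _stage("binarize")(binarize)(imap, config.binarization)
                   for kind, imap in oversampled.items()}
    for op in config.fusion:
        binary_maps[op] = _stage("fuse")(fuse)(binary_maps["cia"], binary_maps["cis"], op)

    truth = _stage("truth")(rasterize_truth)(
        phantom, geometry.oversampled(config.oversample_factor))
    confusions = {name: confusion(bmap, truth, method=name)
                  for name, bmap in binary_maps.items()}
    localizations = {name: localize(bmap, phantom)
                     for name, bmap in binary_maps.items()}
    for name, summ in confusions.items():
        logger.info("confusion[%s]: tp%%=%.2f tn%%=%.2f fp%%=%.2f fn%%=%.2f",
                    name, summ.tp_pct, summ.tn_pct, summ.fp_pct, summ.fn_pct)

    result = PipelineResult(
        config=config, phantom=phantom, grid=grid, table=table,
        index_maps=index_maps, oversampled_maps=oversampled,
        binary_maps=binary_maps, truth=truth, confusions=confusions,
        localizations=localizations)
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    from .io import save_map_png

    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    provenance = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "phantom": result.phantom.name,
        "nodulescan_version": __version__,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    result.table.to_csv(outdir / "indices.csv", index=False)
    result.truth.to_csv(outdir / "truth.csv")
    for kind, imap in result.oversampled_maps.items():
        imap.to_csv(outdir / f"map_{kind}.csv")
        save_map_png(imap.values, imap.geometry, outdir / f"map_{kind}.png",
                     title=kind.upper())
    for name, bmap in result.binary_maps.items():
        bmap.to_csv(outdir / f"mask_{name}.csv")
        save_map_png(bmap.mask.astype(float), bmap.geometry,
                     outdir / f"mask_{name}.png", title=name.upper())
    conf = pd.concat({name: s.to_frame() for name, s in result.confusions.items()},
                     names=["method", "cell"])
    conf.to_csv(outdir / "confusion.csv")
    loc = pd.concat({name: rep.to_frame() for name, rep in result.localizations.items()},
                    names=["method", "row"])
    loc.to_csv(outdir / "localization.csv")
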