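"""Phantom / tissue scene description and ground-truth rasterization.

A :class:`PhantomSpec` describes a slab of soft material (agar or excised
liver) resting on a steel reflector plate, with zero or more stiff agar
inclusions buried inside it.  Coordinates are millimetres: X and Y span the
lateral plane (X along the slab length, Y along its width), Z is depth from
the probed surface.  The origin sits at the corner of the scan area.

Because the pulse-echo measurement integrates the full through-thickness
path to the plate and back, the ground truth used to score detection maps
is the *lateral projection* of each inclusion: a disk for a sphere, an
ellipse for an ellipsoid, a capsule (stadium) for a syringe-channel
filling.  :func:`rasterize_truth` marks every grid cell whose centre falls
strictly inside any such footprint.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .grid import GridGeometry

__all__ = [
    "InclusionSpec",
    "PhantomSpec",
    "GroundTruthMask",
    "builtin_scenario",
    "rasterize_truth",
    "BUILTIN_SCENARIOS",
]

_SHAPES = ("sphere", "ellipsoid", "channel")


@dataclass
class InclusionSpec:
    """One stiff inclusion (nodule mimic) inside the phantom.

    Parameters
    ----------
    id
        Label used in reports.
    shape
        ``sphere`` (regular nodule mimics), ``ellipsoid`` (flattened
        deposits) or ``channel`` (elongated syringe-track / vessel filling,
        modelled as an X-aligned capsule).
    center
        (x, y, z) of the inclusion centre, mm.
    principal_sizes
        Full extents in mm: ``(diameter,)`` for a sphere, ``(dx, dy, dz)``
        for an ellipsoid, ``(length, width, height)`` for a channel.
    amplitude_contrast
        Relative plate-echo amplitude reduction when the beam path crosses
        the inclusion completely; 0.6 means the echo drops to 40 % of the
        background amplitude.
    bubble_density
        Expected number of air-bubble defects per mm^3 of inclusion volume.
        Bubbles add extra, randomly placed attenuation.
    """

    id: str
    shape: str
    center: tuple[float, float, float]
    principal_sizes: tuple[float, ...]
    amplitude_contrast: float
    bubble_density: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        self.center = tuple(float(c) for c in self.center)
        self.principal_sizes = tuple(float(s) for s in self.principal_sizes)
        if self.shape == "sphere" and len(self.principal_sizes) == 1:
            d = self.principal_sizes[0]
            self.principal_sizes = (d, d, d)
        if len(self.principal_sizes) != 3:
            raise ValueError("principal_sizes must give three extents "
                             "(a single diameter is accepted for spheres)")
        if any(s <= 0 for s in self.principal_sizes):
            raise ValueError("all extents must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must lie in [0, 1]")
        if self.bubble_density < 0:
            raise ValueError("bubble_density must be >= 0")

    # -- lateral footprint -------------------------------------------------
    def contains_lateral(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Strict-interior test of (x, y) against the lateral projection."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cx, cy, _ = self.center
        sx, sy, _ = self.principal_sizes
        if self.shape == "sphere":
            r = sx / 2.0
            return (x - cx) ** 2 + (y - cy) ** 2 < r * r
        if self.shape == "ellipsoid":
            a, b = sx / 2.0, sy / 2.0
            return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 < 1.0
        # channel: capsule aligned with X
        half_core = max(sx - sy, 0.0) / 2.0
        r = sy / 2.0
        dx = np.maximum(np.abs(x - cx) - half_core, 0.0)
        return dx ** 2 + (y - cy) ** 2 < r * r

    def lateral_bounds(self) -> tuple[float, float, float, float]:
        cx, cy, _ = self.center
        sx, sy, _ = self.principal_sizes
        return (cx - sx / 2, cx + sx / 2, cy - sy / 2, cy + sy / 2)

    def volume_mm3(self) -> float:
        sx, sy, sz = self.principal_sizes
        if self.shape == "sphere":
            return 4.0 / 3.0 * np.pi * (sx / 2.0) ** 3
        if self.shape == "ellipsoid":
            return 4.0 / 3.0 * np.pi * (sx / 2) * (sy / 2) * (sz / 2)
        # capsule: cylinder core + spherical caps, circular cross-section sy
        r = sy / 2.0
        core = max(sx - sy, 0.0)
        return np.pi * r * r * core + 4.0 / 3.0 * np.pi * r ** 3


@dataclass
class PhantomSpec:
    """Slab phantom with buried inclusions.

    ``length`` spans X, ``width`` spans Y, ``thickness`` spans Z (depth).
    ``background_heterogeneity`` is the fractional RMS jitter of the plate
    echo amplitude from point to point in inclusion-free regions; excised
    liver is far more heterogeneous than a poured agar block.  ``seed``
    fixes the random placement of bubble defects so a phantom is a single
    reproducible object.
    """

    name: str
    length: float
    width: float
    thickness: float
    background: str = "agar"
    background_heterogeneity: float = 0.02
    inclusions: list[InclusionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.thickness) <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.background not in ("agar", "liver"):
            raise ValueError("background must be 'agar' or 'liver'")
        if self.background_heterogeneity < 0:
            raise ValueError("background_heterogeneity must be >= 0")
        fixed = []
        for inc in self.inclusions:
            if isinstance(inc, dict):
                inc = InclusionSpec(**inc)
            fixed.append(inc)
            x0, x1, y0, y1 = inc.lateral_bounds()
            _, _, cz = inc.center
            sz = inc.principal_sizes[2]
            if (x0 < 0 or x1 > self.length or y0 < 0 or y1 > self.width
                    or cz - sz / 2 < 0 or cz + sz / 2 > self.thickness):
                raise ValueError(f"inclusion {inc.id!r} does not fit inside the phantom volume")
        self.inclusions = fixed

    # -- plain-text config round-trip --------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PhantomSpec":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = yaml.safe_load(io.StringIO(text))
        doc["inclusions"] = [InclusionSpec(**inc) for inc in doc.get("inclusions", [])]
        return cls(**doc)


@dataclass
class GroundTruthMask:
    """Boolean inclusion footprint rasterized on a scan grid."""

    geometry: GridGeometry
    values: np.ndarray  # bool, shape (n_y, n_x)
    phantom_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (self.geometry.n_y, self.geometry.n_x):
            raise ValueError("mask shape does not match its grid geometry")

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values.astype(int), fmt="%d", delimiter=",")


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

def _agar_fig5() -> PhantomSpec:
    # Agar block with four buried agar spheres of decreasing diameter
    # (12, 9, 6, 3 mm left to right), centred at half depth (7.5 mm).
    # The scanned area is 72 x 14 mm; the spec of the block itself is
    # 100 x 60 x 15 mm.  Exact lateral centres are not documented for the
    # physical phantom, so the four spheres are spaced evenly along the
    # scan area (18 mm apart) on its mid line.
    diameters = (12.0, 9.0, 6.0, 3.0)
    xs = (9.0, 27.0, 45.0, 63.0)
    inclusions = [
        InclusionSpec(
            id=f"sphere_{int(d)}mm",
            shape="sphere",
            center=(x, 7.0, 7.5),
            principal_sizes=(d,),
            amplitude_contrast=0.6,
            bubble_density=0.01,
        )
        for d, x in zip(diameters, xs)
    ]
    return PhantomSpec(
        name="agar_fig5",
        length=100.0,
        width=60.0,
        thickness=15.0,
        background="agar",
        background_heterogeneity=0.02,
        inclusions=inclusions,
        seed=20,
    )


def _liver_sample_like() -> PhantomSpec:
    # Excised-liver-like slab with three irregular agar fillings: a small
    # quasi-spherical deposit (type I), an elongated syringe-channel
    # filling (type II) and a flat vessel filling (type III ellipsoid).
    # Echo contrast over liver inclusions is weak (~20 %) and the
    # background is much more heterogeneous than agar.
    inclusions = [
        InclusionSpec(id="typeI_deposit", shape="sphere",
                      center=(6.0, 8.0, 7.5), principal_sizes=(2.5,),
                      amplitude_contrast=0.2, bubble_density=0.02),
        InclusionSpec(id="typeII_channel", shape="channel",
                      center=(14.0, 18.0, 7.5), principal_sizes=(12.0, 3.0, 3.0),
                      amplitude_contrast=0.2, bubble_density=0.02),
        InclusionSpec(id="typeIII_vessel", shape="ellipsoid",
                      center=(16.0, 26.0, 8.0), principal_sizes=(8.0, 4.0, 3.0),
                      amplitude_contrast=0.2, bubble_density=0.02),
    ]
    return PhantomSpec(
        name="liver_sample_like",
        length=30.0,
        width=40.0,
        thickness=15.0,
        background="liver",
        background_heterogeneity=0.12,
        inclusions=inclusions,
        seed=21,
    )


BUILTIN_SCENARIOS: dict[str, object] = {
    "agar_fig5": _agar_fig5,
    "liver_sample_like": _liver_sample_like,
}

#: default scan area (width_x, width_y) in mm for each built-in scenario
SCENARIO_SCAN_AREAS: dict[str, tuple[float, float]] = {
    "agar_fig5": (72.0, 14.0),
    "liver_sample_like": (24.0, 30.0),
}


def builtin_scenario(name: str) -> PhantomSpec:
    """Return a fully populated built-in phantom scenario by name."""
    try:
        factory = BUILTIN_SCENARIOS[name]
    except KeyError:
        avail = ", ".join(sorted(BUILTIN_SCENARIOS))
        raise KeyError(f"unknown scenario {name!r}; available scenarios: {avail}") from None
    return factory()


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_truth(phantom: PhantomSpec, geometry: GridGeometry) -> GroundTruthMask:
    """Mark grid cells whose centres fall inside any inclusion footprint.

    Cell centres lying exactly on a footprint boundary are background
    (strict interior test).  Raises ``ValueError`` when the grid area is
    not contained in the phantom's lateral extent.
    """
    x_min, x_max, y_min, y_max = geometry.extent
    tol = 1e-9
    if (x_min < -tol or x_max > phantom.length + tol
            or y_min < -tol or y_max > phantom.width + tol):
        raise ValueError(
            f"grid area [{x_min}, {x_max}] x [{y_min}, {y_max}] mm lies outside "
            f"the phantom extent [0, {phantom.length}] x [0, {phantom.width}] mm")
    xx, yy = geometry.meshgrid()
    mask = np.zeros((geometry.n_y, geometry.n_x), dtype=bool)
    for inc in phantom.inclusions:
        mask |= inc.contains_lateral(xx, yy)
    return GroundTruthMask(geometry=geometry, values=mask, phantom_name=phantom.name)
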