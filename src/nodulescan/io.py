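"""Scan-container round-tripping (HDF5 and long-format CSV) and map rendering."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acoustics import PulseModel, ScanGrid
from .grid import GridGeometry

__all__ = ["write_scan", "read_scan", "write_scan_csv", "read_scan_csv", "save_map_png"]

_REQUIRED_ATTRS = ("pitch", "x0", "y0", "sampling_rate", "record_start", "seed",
                   "phantom_name")
_REQUIRED_DATASETS = ("waveforms", "echo_delays")


def write_scan(grid: ScanGrid, path: str | Path) -> None:
    """Write a ScanGrid to an HDF5 container.

    Layout: datasets ``waveforms`` (n_y, n_x, n_t), ``echo_delays``
    (n_y, n_x), ``x_mm`` and ``y_mm`` axes; acquisition metadata as root
    attributes.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=grid.waveforms)
        f.create_dataset("echo_delays", data=grid.echo_delays)
        f.create_dataset("x_mm", data=grid.geometry.x_centers)
        f.create_dataset("y_mm", data=grid.geometry.y_centers)
        f.attrs["pitch"] = grid.geometry.pitch
        f.attrs["x0"] = grid.geometry.x0
        f.attrs["y0"] = grid.geometry.y0
        f.attrs["sampling_rate"] = grid.sampling_rate
        f.attrs["record_start"] = grid.record_start
        f.attrs["seed"] = grid.seed
        f.attrs["phantom_name"] = grid.phantom_name
        f.attrs["pulse_center_frequency"] = grid.pulse.center_frequency
        f.attrs["pulse_fractional_bandwidth_6db"] = grid.pulse.fractional_bandwidth_6db
        f.attrs["pulse_amplitude"] = grid.pulse.amplitude


def read_scan(path: str | Path) -> ScanGrid:
    """Read a ScanGrid back from :func:`write_scan` output.

    A malformed container raises ``KeyError`` naming the first missing
    dataset or attribute.
    """
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise KeyError(f"scan container is missing dataset {name!r}")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise KeyError(f"scan container is missing attribute {name!r}")
        waveforms = f["waveforms"][()]
        delays = f["echo_delays"][()]
        ny, nx = waveforms.shape[:2]
        geometry = GridGeometry(pitch=float(f.attrs["pitch"]), n_x=nx, n_y=ny,
                                x0=float(f.attrs["x0"]), y0=float(f.attrs["y0"]))
        pulse = PulseModel(
            center_frequency=float(f.attrs.get("pulse_center_frequency", 16e6)),
            fractional_bandwidth_6db=float(f.attrs.get("pulse_fractional_bandwidth_6db", 0.25)),
            sampling_rate=float(f.attrs["sampling_rate"]),
            amplitude=float(f.attrs.get("pulse_amplitude", 1.0)),
        )
        return ScanGrid(geometry=geometry, waveforms=waveforms,
                        sampling_rate=float(f.attrs["sampling_rate"]),
                        record_start=float(f.attrs["record_start"]),
                        echo_delays=delays,
                        phantom_name=str(f.attrs["phantom_name"]),
                        seed=int(f.attrs["seed"]), pulse=pulse)


def write_scan_csv(grid: ScanGrid, path: str | Path) -> None:
    """Long-format CSV alternative: one row per (point, sample).

    Metadata travels in ``# key=value`` header comment lines.
    """
    path = Path(path)
    ny, nx, nt = grid.waveforms.shape
    j, i, s = np.meshgrid(np.arange(ny), np.arange(nx), np.arange(nt), indexing="ij")
    df = pd.DataFrame({
        "i": i.ravel(), "j": j.ravel(), "sample": s.ravel(),
        "amplitude": grid.waveforms.ravel(),
    })
    header = "".join(
        f"# {key}={val}\n" for key, val in [
            ("pitch", grid.geometry.pitch), ("x0", grid.geometry.x0),
            ("y0", grid.geometry.y0), ("n_x", nx), ("n_y", ny), ("n_t", nt),
            ("sampling_rate", grid.sampling_rate), ("record_start", grid.record_start),
            ("seed", grid.seed), ("phantom_name", grid.phantom_name),
            ("echo_delays", ";".join(f"{d:.12g}" for d in grid.echo_delays.ravel())),
        ])
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_scan_csv(path: str | Path) -> ScanGrid:
    """Read a ScanGrid from :func:`write_scan_csv` output."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    for key in ("pitch", "x0", "y0", "n_x", "n_y", "n_t", "sampling_rate",
                "record_start", "seed"):
        if key not in meta:
            raise KeyError(f"scan CSV is missing metadata {key!r}")
    nx, ny, nt = int(meta["n_x"]), int(meta["n_y"]), int(meta["n_t"])
    waveforms = np.zeros((ny, nx, nt))
    waveforms[df["j"], df["i"], df["sample"]] = df["amplitude"]
    delays = np.fromstring(meta.get("echo_delays", ""), sep=";").reshape(ny, nx) \
        if meta.get("echo_delays") else np.zeros((ny, nx))
    geometry = GridGeometry(pitch=float(meta["pitch"]), n_x=nx, n_y=ny,
                            x0=float(meta["x0"]), y0=float(meta["y0"]))
    return ScanGrid(geometry=geometry, waveforms=waveforms,
                    sampling_rate=float(meta["sampling_rate"]),
                    record_start=float(meta["record_start"]), echo_delays=delays,
                    phantom_name=meta.get("phantom_name", ""), seed=int(meta["seed"]),
                    pulse=PulseModel(sampling_rate=float(meta["sampling_rate"])))


def save_map_png(values: np.ndarray, geometry: GridGeometry, path: str | Path,
                 title: str = "") -> None:
    """Render a map with the usual convention: yellow = inclusion, blue = not."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, max(2.0, 6 * geometry.n_y / geometry.n_x)))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    x_min, x_max, y_min, y_max = geometry.extent
    im = ax.imshow(np.asarray(values, dtype=float), origin="lower", cmap="viridis",
                   extent=(x_min, x_max, y_min, y_max), vmin=0.0, vmax=1.0,
                   interpolation="nearest")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
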