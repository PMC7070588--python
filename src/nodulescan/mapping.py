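"""Index maps: oversampling, unsupervised binarization, AND/OR fusion.

Per-point CIA/CIS values become a scalar field on the scan grid, are
interpolated onto a finer sub-pixel grid (default 6x, turning the 2 mm
pitch into 0.33 mm), binarized with an unsupervised two-class rule
(1-D k-means by default, Otsu as an alternative), and the two binary maps
are fused element-wise: AND keeps the high-confidence core of inclusions,
OR keeps their full extent including edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .grid import GridGeometry

__all__ = [
    "IndexMap",
    "BinaryMap",
    "map_from_table",
    "oversample",
    "binarize",
    "fuse",
]

logger = logging.getLogger(__name__)


@dataclass
class IndexMap:
    """Scalar index field on a (possibly oversampled) scan grid."""

    values: np.ndarray          # (n_y, n_x), in [0, 1]
    geometry: GridGeometry
    kind: str                   # "cia" or "cis"
    oversample_factor: int = 1  # 1 = native pitch

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_y, self.geometry.n_x):
            raise ValueError("index values do not match the grid geometry")
        if np.any(self.values < -1e-9) or np.any(self.values > 1.0 + 1e-9):
            raise ValueError("index values must lie in [0, 1]")
        self.kind = self.kind.lower()

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, fmt="%.6f", delimiter=",")


@dataclass
class BinaryMap:
    """Classified inclusion mask on the same grid as its source map(s)."""

    mask: np.ndarray            # bool, (n_y, n_x)
    geometry: GridGeometry
    source: str                 # "cia", "cis", "and", "or"
    threshold: float | None = None
    method: str = "kmeans"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.geometry.n_y, self.geometry.n_x):
            raise ValueError("mask does not match the grid geometry")

    @property
    def n_positive(self) -> int:
        return int(self.mask.sum())

    def to_csv(self, path) -> None:
        np.savetxt(path, self.mask.astype(int), fmt="%d", delimiter=",")


def map_from_table(table: pd.DataFrame, geometry: GridGeometry, kind: str) -> IndexMap:
    """Assemble an IndexMap from an index table's ``cia`` or ``cis`` column."""
    kind = kind.lower()
    if kind not in table.columns:
        raise KeyError(f"index table has no column {kind!r}")
    values = np.zeros((geometry.n_y, geometry.n_x))
    values[table["j"].to_numpy(int), table["i"].to_numpy(int)] = table[kind].to_numpy(float)
    return IndexMap(values=values, geometry=geometry, kind=kind)


def oversample(imap: IndexMap, factor: int = 6, method: str = "bilinear") -> IndexMap:
    """Interpolate the index field onto a ``factor``-fold finer grid.

    ``bilinear`` (default) interpolates between native cell centres with
    edge clamping; ``nearest`` replicates each native classification into
    its ``factor x factor`` block of sub-pixels.
    """
    if factor < 1:
        raise ValueError(f"oversample factor must be >= 1, got {factor}")
    if factor == 1:
        return IndexMap(imap.values.copy(), imap.geometry, imap.kind,
                        imap.oversample_factor)
    sub_geom = imap.geometry.oversampled(factor)
    # sub-pixel centres expressed in native index coordinates
    u = (np.arange(sub_geom.n_x) + 0.5) / factor - 0.5
    v = (np.arange(sub_geom.n_y) + 0.5) / factor - 0.5
    vv, uu = np.meshgrid(v, u, indexing="ij")
    order = {"bilinear": 1, "nearest": 0}.get(method)
    if order is None:
        raise ValueError(f"unknown interpolation method {method!r}")
    values = map_coordinates(imap.values, [vv, uu], order=order, mode="nearest")
    return IndexMap(values=np.clip(values, 0.0, 1.0), geometry=sub_geom,
                    kind=imap.kind, oversample_factor=imap.oversample_factor * factor)


def _kmeans_threshold(values: np.ndarray) -> tuple[np.ndarray, float]:
    km = KMeans(n_clusters=2, n_init=10, random_state=0)
    labels = km.fit_predict(values.reshape(-1, 1))
    means = km.cluster_centers_.ravel()
    if np.isclose(means[0], means[1]):
        # degenerate split: conservative tie-break toward background
        return np.zeros(values.size, dtype=bool), float(values.max())
    high = int(np.argmax(means))
    mask = labels == high
    threshold = (values[~mask].max() + values[mask].min()) / 2.0
    return mask, float(threshold)


def binarize(imap: IndexMap, method: str = "kmeans") -> BinaryMap:
    """Two-class unsupervised split of an index map; high values = inclusion.

    A constant map yields an all-background mask with a warning: with no
    amplitude or shape variation there is nothing to detect.
    """
    flat = imap.values.ravel()
    if np.ptp(flat) < 1e-12:
        warnings.warn(f"{imap.kind} map is constant; classifying everything as background",
                      stacklevel=2)
        return BinaryMap(mask=np.zeros_like(imap.values, dtype=bool),
                         geometry=imap.geometry, source=imap.kind,
                         threshold=None, method=method)
    if method == "kmeans":
        mask, threshold = _kmeans_threshold(flat)
        mask = mask.reshape(imap.values.shape)
    elif method == "otsu":
        threshold = float(threshold_otsu(flat))
        mask = imap.values > threshold
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    logger.info("binarized %s map (%s): threshold %.4f, %d / %d sub-pixels positive",
                imap.kind, method, threshold, int(mask.sum()), mask.size)
    return BinaryMap(mask=mask, geometry=imap.geometry, source=imap.kind,
                     threshold=threshold, method=method)


def fuse(a: BinaryMap, b: BinaryMap, op: str) -> BinaryMap:
    """Element-wise AND / OR combination of two binary maps."""
    if not a.geometry.matches(b.geometry):
        raise ValueError("binary maps to fuse must share the same grid geometry")
    op = op.lower()
    if op == "and":
        mask = a.mask & b.mask
    elif op == "or":
        mask = a.mask | b.mask
    else:
        raise ValueError(f"fusion operator must be 'and' or 'or', got {op!r}")
    return BinaryMap(mask=mask, geometry=a.geometry, source=op,
                     threshold=None, method=f"{a.source} {op} {b.source}")
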