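"""Scoring of binary detection maps against ground truth.

Two complementary views: a confusion matrix over classified sub-pixels
with row-normalized percentages (each percentage is taken within its
ground-truth class, i.e. TN% = TN / (TN + FP) * 100 and TP% =
TP / (TP + FN) * 100), and per-inclusion centre-localization error from
connected-component centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .mapping import BinaryMap
from .phantom import GroundTruthMask, PhantomSpec

__all__ = [
    "ConfusionSummary",
    "confusion",
    "InclusionLocalization",
    "LocalizationReport",
    "localize",
]


@dataclass
class ConfusionSummary:
    """Sub-pixel confusion counts and row-normalized percentages."""

    tn: int
    fp: int
    fn: int
    tp: int
    method: str = ""

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def n_negative(self) -> int:
        """Ground-truth background sub-pixels."""
        return self.tn + self.fp

    @property
    def n_positive(self) -> int:
        """Ground-truth inclusion sub-pixels."""
        return self.fn + self.tp

    @property
    def tn_pct(self) -> float:
        return 100.0 * self.tn / self.n_negative if self.n_negative else float("nan")

    @property
    def fp_pct(self) -> float:
        return 100.0 * self.fp / self.n_negative if self.n_negative else float("nan")

    @property
    def fn_pct(self) -> float:
        return 100.0 * self.fn / self.n_positive if self.n_positive else float("nan")

    @property
    def tp_pct(self) -> float:
        return 100.0 * self.tp / self.n_positive if self.n_positive else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": [self.tn, self.fp, self.fn, self.tp],
             "percent": [self.tn_pct, self.fp_pct, self.fn_pct, self.tp_pct]},
            index=["tn", "fp", "fn", "tp"])

    def pretty(self) -> str:
        """Two-row layout: TN / FP over FN / TP, counts with percentages."""
        return (f"[{self.method}]\n"
                f"  TN {self.tn:>6d} ({self.tn_pct:6.2f}%)   FP {self.fp:>6d} ({self.fp_pct:6.2f}%)\n"
                f"  FN {self.fn:>6d} ({self.fn_pct:6.2f}%)   TP {self.tp:>6d} ({self.tp_pct:6.2f}%)")


def confusion(pred: BinaryMap, truth: GroundTruthMask, method: str = "") -> ConfusionSummary:
    """Count sub-pixel agreement between a binary map and the ground truth."""
    if not pred.geometry.matches(truth.geometry):
        raise ValueError("prediction and ground truth must share the same grid geometry")
    p = pred.mask
    t = truth.values
    return ConfusionSummary(
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tp=int(np.sum(p & t)),
        method=method or pred.source,
    )


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------

@dataclass
class InclusionLocalization:
    """Match between one inclusion and a detected connected component."""

    inclusion_id: str
    nominal_center: tuple[float, float]          # (x, y) mm
    detected_center: tuple[float, float] | None  # component centroid, mm
    error_mm: float                              # inf when undetected
    detected: bool


@dataclass
class LocalizationReport:
    """Per-inclusion localization outcome for one binary map."""

    entries: list[InclusionLocalization] = field(default_factory=list)
    method: str = ""

    @property
    def all_detected(self) -> bool:
        return bool(self.entries) and all(e.detected for e in self.entries)

    @property
    def max_error_mm(self) -> float:
        return max((e.error_mm for e in self.entries), default=float("nan"))

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "inclusion": e.inclusion_id,
            "nominal_x_mm": e.nominal_center[0],
            "nominal_y_mm": e.nominal_center[1],
            "detected_x_mm": e.detected_center[0] if e.detected else np.nan,
            "detected_y_mm": e.detected_center[1] if e.detected else np.nan,
            "error_mm": e.error_mm,
            "detected": e.detected,
        } for e in self.entries]
        return pd.DataFrame(rows)


def localize(pred: BinaryMap, phantom: PhantomSpec) -> LocalizationReport:
    """Match connected components of a binary map to the phantom's inclusions.

    Components are extracted with 8-connectivity; their centroids (in mm)
    are matched one-to-one to nominal inclusion centres greedily by
    increasing Euclidean distance.  An inclusion left without a component
    is reported as undetected; an empty prediction is not an error, it
    simply detects nothing.  An inclusion counts as detected as soon as a
    matched component exists, whatever its size - a single sub-pixel over
    the smallest nodule is still a find.
    """
    geom = pred.geometry
    labels = label(pred.mask, connectivity=2)
    centroids = []
    for region in regionprops(labels):
        row, col = region.centroid
        centroids.append((geom.x0 + col * geom.pitch, geom.y0 + row * geom.pitch))

    nominal = [(inc.id, (inc.center[0], inc.center[1])) for inc in phantom.inclusions]
    pairs = sorted(
        ((np.hypot(cx - nx, cy - ny), ic, kc)
         for ic, (_, (nx, ny)) in enumerate(nominal)
         for kc, (cx, cy) in enumerate(centroids)),
        key=lambda t: t[0])
    matched_inc: dict[int, tuple[int, float]] = {}
    used_comp: set[int] = set()
    for dist, ic, kc in pairs:
        if ic in matched_inc or kc in used_comp:
            continue
        matched_inc[ic] = (kc, dist)
        used_comp.add(kc)

    entries = []
    for ic, (inc_id, center) in enumerate(nominal):
        if ic in matched_inc:
            kc, dist = matched_inc[ic]
            entries.append(InclusionLocalization(
                inclusion_id=inc_id, nominal_center=center,
                detected_center=centroids[kc], error_mm=float(dist), detected=True))
        else:
            entries.append(InclusionLocalization(
                inclusion_id=inc_id, nominal_center=center,
                detected_center=None, error_mm=float("inf"), detected=False))
    return LocalizationReport(entries=entries, method=pred.source)
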