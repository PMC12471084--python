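"""Registration quality metrics: DSC, TRE, robust aggregates, success rate.

The robust aggregates follow the convention of trimming the unfavorable
tail: robust DSC averages the top fraction of cases, robust TRE the
smallest-error fraction (trim fraction configurable, default keep 75%).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .deform import sample_field_at_points
from .volume_io import LabelMask, LandmarkSet

__all__ = ["CaseMetrics", "dsc", "tre", "warp_landmarks", "robust_aggregate",
           "success_rate", "aggregate_metrics", "write_metrics_csv"]


@dataclass
class CaseMetrics:
    case_id: str
    dsc: float
    tre_mm: float
    folding_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"dsc out of [0,1]: {self.dsc}")
        if self.tre_mm < 0:
            raise ValueError(f"negative TRE: {self.tre_mm}")
        if not (0.0 <= self.folding_fraction <= 1.0):
            raise ValueError(f"folding fraction out of [0,1]: {self.folding_fraction}")


def dsc(a, b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks give 1.0."""
    a_arr = a.data if isinstance(a, LabelMask) else np.asarray(a)
    b_arr = b.data if isinstance(b, LabelMask) else np.asarray(b)
    if a_arr.shape != b_arr.shape:
        raise ValueError(f"shape mismatch: {a_arr.shape} vs {b_arr.shape}")
    a_bin = a_arr > 0.5
    b_bin = b_arr > 0.5
    denom = int(a_bin.sum()) + int(b_bin.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a_bin, b_bin).sum()) / denom


def tre(fixed_lms: LandmarkSet, warped_lms: LandmarkSet, spacing_mm) -> float:
    """Root-mean-square Euclidean distance (mm) between corresponding landmarks."""
    if len(fixed_lms) != len(warped_lms):
        raise ValueError("landmark sets differ in cardinality")
    if list(fixed_lms.ids) != list(warped_lms.ids):
        order = {lid: i for i, lid in enumerate(warped_lms.ids)}
        try:
            perm = [order[lid] for lid in fixed_lms.ids]
        except KeyError as exc:
            raise ValueError(f"landmark id mismatch: {exc}") from exc
        warped_pts = warped_lms.points[perm]
    else:
        warped_pts = warped_lms.points
    sp = np.asarray(spacing_mm, dtype=np.float64)
    delta = (fixed_lms.points - warped_pts) * sp
    return float(np.sqrt((delta ** 2).sum(axis=1).mean()))


def warp_landmarks(fixed_lms: LandmarkSet, field: np.ndarray) -> LandmarkSet:
    """Map fixed-frame landmarks into the moving frame: p -> p + phi(p)."""
    moved = fixed_lms.points + sample_field_at_points(field, fixed_lms.points)
    return LandmarkSet(moved, list(fixed_lms.ids))


def robust_aggregate(per_case: Sequence[float], kind: str,
                     keep_fraction: float = 0.75) -> float:
    """Mean over the favorable keep_fraction of cases.

    ``kind='dsc'`` keeps the largest values, ``kind='tre'`` the smallest;
    keep count is ceil(keep_fraction * n).
    """
    if len(per_case) == 0:
        raise ValueError("empty metric list")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction out of (0,1]: {keep_fraction}")
    if kind not in ("dsc", "tre"):
        raise ValueError(f"unknown metric kind: {kind!r}")
    vals = np.sort(np.asarray(per_case, dtype=np.float64))
    keep = math.ceil(keep_fraction * len(vals))
    kept = vals[-keep:] if kind == "dsc" else vals[:keep]
    return float(kept.mean())


def success_rate(tre_list_mm: Sequence[float], threshold_mm: float = 5.0) -> float:
    if len(tre_list_mm) == 0:
        raise ValueError("empty TRE list")
    arr = np.asarray(tre_list_mm, dtype=np.float64)
    return float((arr < threshold_mm).mean())


def aggregate_metrics(cases: List[CaseMetrics], keep_fraction: float = 0.75,
                      success_threshold_mm: float = 5.0) -> dict:
    dscs = [c.dsc for c in cases]
    tres = [c.tre_mm for c in cases]
    return {
        "dsc": float(np.mean(dscs)),
        "rdsc": robust_aggregate(dscs, "dsc", keep_fraction),
        "tre_mm": float(np.mean(tres)),
        "rtre_mm": robust_aggregate(tres, "tre", keep_fraction),
        "folding_fraction": float(np.mean([c.folding_fraction for c in cases])),
        "success_rate": success_rate(tres, success_threshold_mm),
        "n_cases": len(cases),
    }


def write_metrics_csv(cases: List[CaseMetrics], path,
                      aggregate: Optional[dict] = None) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "dsc", "tre_mm", "folding_fraction"])
        for c in cases:
            writer.writerow([c.case_id, c.dsc, c.tre_mm, c.folding_fraction])
        if aggregate:
            writer.writerow([])
            for key, value in aggregate.items():
                writer.writerow([key, value, "", ""])
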