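"""Segmentation evaluation: VS, HD95, DSC, and paired rater comparisons.

Given a manual mask M and a predicted mask P the three scores are

    VS  = 100 * (1 - |V_M - V_P| / (V_M + V_P))        volume agreement
    DSC = 100 * 2|M n P| / (|M| + |P|)                 spatial overlap
    HD95 = 95th percentile of symmetric surface distances (mm)

where V is the foreground voxel count.  HD95 pools both directed
border-to-border distance sets before taking the percentile (the common
reference behaviour); a max-of-directed variant is available via
``method="max_directed"``.

Empty-mask conventions: if both masks are empty, VS = DSC = 100 (flagged);
if exactly one is empty, VS = DSC = 0; HD95 is undefined (NaN, flagged)
whenever either mask is empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import BinaryMask, CompatibilityError

__all__ = [
    "MetricsReport",
    "volumetric_similarity",
    "surface_distances",
    "hd95",
    "dsc",
    "compare_paired",
    "evaluate_pair",
    "reports_to_frame",
    "write_report_csv",
]


class UndefinedDistanceError(ValueError):
    """Surface distances are undefined for an empty mask."""


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    return data.astype(bool)


def _check_shapes(m: np.ndarray, p: np.ndarray) -> None:
    if m.shape != p.shape:
        raise CompatibilityError(f"mask shapes differ: {m.shape} vs {p.shape}")


def volumetric_similarity(M: BinaryMask | np.ndarray, P: BinaryMask | np.ndarray) -> float:
    """VS in percent; 100 when both masks are empty (convention)."""
    m, p = _as_bool(M), _as_bool(P)
    _check_shapes(m, p)
    vm, vp = int(m.sum()), int(p.sum())
    if vm + vp == 0:
        return 100.0
    return 100.0 * (1.0 - abs(vm - vp) / (vm + vp))


def dsc(M: BinaryMask | np.ndarray, P: BinaryMask | np.ndarray) -> float:
    """Dice similarity coefficient in percent; 100 when both empty."""
    m, p = _as_bool(M), _as_bool(P)
    _check_shapes(m, p)
    vm, vp = int(m.sum()), int(p.sum())
    if vm + vp == 0:
        return 100.0
    inter = int((m & p).sum())
    return 100.0 * 2.0 * inter / (vm + vp)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _border(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face-adjacent background neighbour.

    The outside of the grid counts as background, so foreground touching
    the array edge is border.
    """
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~eroded


def surface_distances(M: BinaryMask | np.ndarray, P: BinaryMask | np.ndarray,
                      spacing: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Directed border-to-border Euclidean distances, in mm, both ways.

    Returns ``(d_M_to_P, d_P_to_M)``: for every border voxel of M the
    minimum anisotropy-aware distance to P's border set, and vice versa.
    Exact Euclidean distance transforms make this O(grid).
    """
    m, p = _as_bool(M), _as_bool(P)
    _check_shapes(m, p)
    if not m.any() or not p.any():
        raise UndefinedDistanceError("surface distances need two nonempty masks")
    bm, bp = _border(m), _border(p)
    spacing = tuple(float(s) for s in spacing)
    # distance of every voxel to the nearest border voxel of the other mask
    dt_to_p = ndimage.distance_transform_edt(~bp, sampling=spacing)
    dt_to_m = ndimage.distance_transform_edt(~bm, sampling=spacing)
    return np.sort(dt_to_p[bm]), np.sort(dt_to_m[bp])


def hd95(M: BinaryMask | np.ndarray, P: BinaryMask | np.ndarray,
         spacing: Sequence[float], method: str = "pooled") -> float:
    """95th-percentile Hausdorff distance in mm.

    ``method="pooled"`` (default) takes the percentile over the union of
    both directed distance sets; ``method="max_directed"`` takes the max
    of the two per-direction percentiles.  Percentiles use linear
    interpolation between order statistics.
    """
    d_mp, d_pm = surface_distances(M, P, spacing)
    if method == "pooled":
        return float(np.percentile(np.concatenate([d_mp, d_pm]), 95))
    if method == "max_directed":
        return float(max(np.percentile(d_mp, 95), np.percentile(d_pm, 95)))
    raise ValueError(f"unknown HD95 method {method!r}")


def compare_paired(scores_a: Sequence[float], scores_b: Sequence[float]
                   ) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p-value for paired scores.

    Zero differences are discarded; the exact null distribution is used
    for n <= 25 remaining pairs (otherwise the normal approximation).
    Returns ``(p_value, degenerate)`` where ``degenerate`` flags the
    all-differences-zero case (p = 1 by convention).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score lists must be 1D and equal length")
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0, True
    method = "exact" if nz.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                             method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                             method="approx")
    return float(res.pvalue), False


@dataclass
class MetricsReport:
    """All three scores for one (M, P) pair, with empty-mask flags."""

    subject_id: str
    vs_percent: float
    hd95_mm: float          # NaN when undefined
    dsc_percent: float
    m_empty: bool
    p_empty: bool

    @property
    def hd95_defined(self) -> bool:
        return not np.isnan(self.hd95_mm)


def evaluate_pair(M: BinaryMask | np.ndarray, P: BinaryMask | np.ndarray,
                  spacing: Sequence[float], subject_id: str = "") -> MetricsReport:
    """Bundle VS, HD95 and DSC for one mask pair, applying conventions."""
    m, p = _as_bool(M), _as_bool(P)
    _check_shapes(m, p)
    m_empty, p_empty = not m.any(), not p.any()
    vs = volumetric_similarity(m, p)
    d = dsc(m, p)
    h = np.nan if (m_empty or p_empty) else hd95(m, p, spacing)
    return MetricsReport(subject_id=subject_id, vs_percent=vs, hd95_mm=h,
                         dsc_percent=d, m_empty=m_empty, p_empty=p_empty)


def reports_to_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "vs_percent": r.vs_percent,
            "hd95_mm": r.hd95_mm,
            "dsc_percent": r.dsc_percent,
            "m_empty": r.m_empty,
            "p_empty": r.p_empty,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def summarize(reports: Sequence[MetricsReport]) -> dict:
    """Median and IQR per metric, HD95 over defined values only."""
    df = reports_to_frame(reports)
    out = {}
    for col in ("vs_percent", "hd95_mm", "dsc_percent"):
        vals = df[col].dropna()
        if len(vals) == 0:
            out[col] = {"median": np.nan, "q1": np.nan, "q3": np.nan}
        else:
            out[col] = {
                "median": float(vals.median()),
                "q1": float(vals.quantile(0.25)),
                "q3": float(vals.quantile(0.75)),
            }
    return out


def write_report_csv(reports: Sequence[MetricsReport], path: str | Path) -> pd.DataFrame:
    """Per-subject CSV plus a median (IQR) summary row appended at the end."""
    df = reports_to_frame(reports)
    summ = summarize(reports)
    summary_row = {
        "subject_id": "median(IQR)",
        "vs_percent": summ["vs_percent"]["median"],
        "hd95_mm": summ["hd95_mm"]["median"],
        "dsc_percent": summ["dsc_percent"]["median"],
        "m_empty": "",
        "p_empty": "",
    }
    out = pd.concat([df, pd.DataFrame([summary_row])], ignore_index=True)
    out.to_csv(path, index=False)
    return out
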