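"""Contour-agreement metrics and cross-algorithm statistics.

Dice, mean slicewise Hausdorff distance (MSHD), centre-of-mass shift,
volume-change tabulation, one-way ANOVA and the point-biserial correlation
used to relate metric values to ordinal clinical-utility scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .image_model import ROIMask

__all__ = [
    "dice",
    "mshd",
    "MSHDResult",
    "com_distance",
    "volume_change_table",
    "one_way_anova",
    "point_biserial",
    "score_to_binary_group",
    "MetricRecord",
]


@dataclass
class MetricRecord:
    """One evaluated (patient, ROI, algorithm) triple."""

    patient: str
    roi: str
    algorithm: str
    dice: float
    mshd_mm: float
    com_distance_cm: float | None = None
    volume_pre_cm3: float | None = None
    volume_mid_cm3: float | None = None
    physician_score: int | None = None


def _check_same_grid(a: ROIMask, b: ROIMask) -> None:
    if a.grid != b.grid:
        raise ValueError("masks must live on the same grid")


def dice(a: ROIMask, b: ROIMask) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)`` on voxel counts."""
    _check_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        warnings.warn("both masks empty; Dice defined as 1", stacklevel=2)
        return 1.0
    inter = int(np.count_nonzero(a.labels & b.labels))
    return 2.0 * inter / (na + nb)


def _slice_boundary_points(labels2d: np.ndarray, spacing_xy) -> np.ndarray:
    """In-plane world-mm coordinates of boundary voxel centres of a 2-D mask.

    A voxel is a boundary voxel if any of its 4 in-plane neighbours
    (or the image edge) is background.
    """
    padded = np.pad(labels2d, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = labels2d & ~interior
    ij = np.argwhere(boundary)
    return ij * np.asarray(spacing_xy)


@dataclass
class MSHDResult:
    """Mean slicewise Hausdorff distance with bookkeeping."""

    mshd_mm: float
    n_slices_compared: int
    n_slices_one_sided: int
    per_slice_mm: list


def mshd_detail(a: ROIMask, b: ROIMask, one_sided_penalty_mm: float | None = None) -> MSHDResult:
    """Slicewise symmetric Hausdorff distances and their mean.

    Per axial slice (third axis) where *both* masks are non-empty, the
    symmetric Hausdorff distance between the two boundary point sets is
    computed in-plane (2-D world mm).  Slices where exactly one mask is
    present are excluded from the mean by default; if
    ``one_sided_penalty_mm`` is given they contribute that penalty instead.
    """
    _check_same_grid(a, b)
    spacing_xy = a.grid.spacing[:2]
    per_slice: list[float] = []
    n_one_sided = 0
    nz = a.grid.dims[2]
    for k in range(nz):
        sa = a.labels[:, :, k]
        sb = b.labels[:, :, k]
        ha, hb = sa.any(), sb.any()
        if not ha and not hb:
            continue
        if ha != hb:
            n_one_sided += 1
            if one_sided_penalty_mm is not None:
                per_slice.append(float(one_sided_penalty_mm))
            continue
        pa = _slice_boundary_points(sa, spacing_xy)
        pb = _slice_boundary_points(sb, spacing_xy)
        d = cdist(pa, pb)
        hausdorff = max(d.min(axis=1).max(), d.min(axis=0).max())
        per_slice.append(float(hausdorff))
    if not per_slice:
        raise ValueError("no comparable slices: masks never co-occur on a slice")
    return MSHDResult(
        mshd_mm=float(np.mean(per_slice)),
        n_slices_compared=len(per_slice),
        n_slices_one_sided=n_one_sided,
        per_slice_mm=per_slice,
    )


def mshd(a: ROIMask, b: ROIMask, one_sided_penalty_mm: float | None = None) -> float:
    """Mean slicewise Hausdorff distance in mm (see :func:`mshd_detail`)."""
    return mshd_detail(a, b, one_sided_penalty_mm).mshd_mm


def com_distance(a: ROIMask, b: ROIMask) -> float:
    """Euclidean distance between unweighted mask centroids, in cm."""
    d_mm = float(np.linalg.norm(a.centroid_mm() - b.centroid_mm()))
    return d_mm / 10.0


def volume_change_table(
    pre_volumes_cm3, mid_volumes_cm3, patient_ids=None
) -> dict:
    """Tabulate per-patient volume change between two time points.

    Percent difference is ``100 * (pre - mid) / pre`` (positive = shrinkage),
    rounded to 1 decimal per patient.  Returns a dict with the per-patient
    table (:class:`pandas.DataFrame`), column means at the reported
    precision, and shrink/growth counts.
    """
    pre = np.asarray(pre_volumes_cm3, dtype=float)
    mid = np.asarray(mid_volumes_cm3, dtype=float)
    if pre.shape != mid.shape or pre.ndim != 1:
        raise ValueError("pre and mid volume lists must be equal-length 1-D")
    if np.any(pre <= 0):
        raise ValueError("pre-treatment volumes must be positive")
    if patient_ids is None:
        patient_ids = list(range(1, len(pre) + 1))
    pct = 100.0 * (pre - mid) / pre
    table = pd.DataFrame(
        {
            "patient": patient_ids,
            "volume_pre_cm3": pre,
            "volume_mid_cm3": mid,
            "percent_difference": np.round(pct, 1),
        }
    )
    decreased = int(np.sum(mid < pre))
    increased = int(np.sum(mid > pre))
    increases_over_10pct = int(np.sum((mid > pre) & (np.abs(pct) > 10.0)))
    return {
        "table": table,
        "mean_pre_cm3": float(np.round(pre.mean(), 2)),
        "mean_mid_cm3": float(np.round(mid.mean(), 2)),
        "mean_percent_difference": float(np.round(pct.mean(), 1)),
        "n_decreased": decreased,
        "n_increased": increased,
        "n_increased_over_10pct": increases_over_10pct,
    }


def one_way_anova(groups) -> tuple[float, float, bool]:
    """Classical one-way ANOVA from between/within sums of squares.

    Returns ``(F, p, significant_at_0.05)``.  Implemented from the textbook
    decomposition rather than delegating to a library routine; the p-value
    uses the F survival function.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    n_total = sum(len(g) for g in groups)
    grand_mean = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand_mean) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ss_within <= 0:
        if ss_between <= 0:
            raise ValueError("zero variance everywhere; ANOVA undefined")
        return float("inf"), 0.0, True
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p_value = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p_value, p_value < 0.05


def score_to_binary_group(scores) -> np.ndarray:
    """Map ordinal clinical-utility scores to binary classes.

    Score 1 (no edits required) -> class 0; scores 2 and 3 (minor or major
    edits required) -> class 1.
    """
    s = np.asarray(scores, dtype=int)
    if not np.all(np.isin(s, (1, 2, 3))):
        raise ValueError("scores must be in {1, 2, 3}")
    return (s >= 2).astype(int)


def point_biserial(binary_group, values) -> tuple[float, float]:
    """Point-biserial correlation between a binary grouping and values.

    ``r = (M1 - M0) / s * sqrt(n1 * n0 / n^2)`` with ``s`` the full-sample
    (population) standard deviation; algebraically identical to the Pearson
    correlation of the 0/1 indicator with the values.  The p-value comes
    from the equivalent t test with ``n - 2`` degrees of freedom.
    """
    g = np.asarray(binary_group, dtype=int)
    v = np.asarray(values, dtype=float)
    if g.shape != v.shape or g.ndim != 1:
        raise ValueError("group and values must be equal-length 1-D")
    if not np.all(np.isin(g, (0, 1))):
        raise ValueError("binary_group must contain only 0 and 1")
    n1 = int(g.sum())
    n0 = len(g) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    n = len(g)
    s = v.std(ddof=0)
    if s == 0:
        return 0.0, 1.0
    m1 = v[g == 1].mean()
    m0 = v[g == 0].mean()
    r = (m1 - m0) / s * np.sqrt(n1 * n0 / n**2)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p
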