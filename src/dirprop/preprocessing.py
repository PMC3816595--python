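"""Shared registration preprocessing.

Rigid pre-alignment by blockwise local correlation, piecewise-linear
histogram matching, and Gaussian multi-resolution pyramids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import (
    ImageGrid,
    RigidTransform,
    ScalarImage,
    trilinear_sample,
)

__all__ = [
    "PyramidSchedule",
    "RigidSearchConfig",
    "rigid_local_correlation",
    "histogram_match",
    "build_pyramid",
    "pyramid_grid",
]


@dataclass(frozen=True)
class PyramidSchedule:
    """Coarse-to-fine downsampling factors with per-level iteration caps
    and field-smoothing sigmas (mm)."""

    factors: tuple[int, ...]
    iterations: tuple[int, ...]
    smoothing_sigmas_mm: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(int(f) for f in self.factors))
        object.__setattr__(self, "iterations", tuple(int(i) for i in self.iterations))
        object.__setattr__(
            self, "smoothing_sigmas_mm", tuple(float(s) for s in self.smoothing_sigmas_mm)
        )
        n = len(self.factors)
        if len(self.iterations) != n or len(self.smoothing_sigmas_mm) != n:
            raise ValueError("schedule lists must have equal lengths")
        if n == 0:
            raise ValueError("schedule must have at least one level")
        if any(f2 >= f1 for f1, f2 in zip(self.factors, self.factors[1:])):
            raise ValueError("factors must be strictly decreasing")
        if self.factors[-1] != 1:
            raise ValueError("finest factor must be 1")
        if any(i < 0 for i in self.iterations):
            raise ValueError("iteration counts must be >= 0")
        if any(s < 0 for s in self.smoothing_sigmas_mm):
            raise ValueError("sigmas must be >= 0")

    @property
    def n_levels(self) -> int:
        return len(self.factors)


def pyramid_grid(grid: ImageGrid, factor: int, min_dim: int = 4) -> ImageGrid:
    """Grid downsampled by ``factor`` with per-axis clamping to ``min_dim``.

    A level whose dims would drop below ``min_dim`` voxels on an axis is
    clamped on that axis (with a warning): the effective factor is reduced
    so the axis keeps at least ``min_dim`` samples.
    """
    dims = []
    clamped = False
    for d in grid.dims:
        nd = int(np.ceil(d / factor))
        if nd < min_dim:
            nd = min(d, min_dim)
            clamped = True
        dims.append(nd)
    if clamped:
        warnings.warn(
            f"pyramid level factor {factor} clamped to keep >= {min_dim} voxels per axis",
            stacklevel=2,
        )
    spacing = tuple(s * d0 / nd for s, d0, nd in zip(grid.spacing, grid.dims, dims))
    return ImageGrid(tuple(dims), spacing, grid.origin)


def _smooth_and_resample(image: ScalarImage, target: ImageGrid, factor: float) -> ScalarImage:
    """Anti-alias (sigma = 0.5 * factor * spacing) then trilinearly resample."""
    if target == image.grid:
        return image.copy()
    sigma_vox = 0.5 * factor  # mm sigma / spacing = 0.5 * factor voxels
    smoothed = ndimage.gaussian_filter(image.values, sigma_vox, mode="nearest")
    src = ScalarImage(image.grid, smoothed)
    pts = target.voxel_centers()
    return ScalarImage(target, trilinear_sample(src, pts))


def build_pyramid(image: ScalarImage, schedule: PyramidSchedule) -> list[ScalarImage]:
    """Gaussian pyramid of ``image``, coarse to fine; finest level is the
    original image untouched."""
    levels = []
    for factor in schedule.factors:
        if factor == 1:
            levels.append(image.copy())
            continue
        grid = pyramid_grid(image.grid, factor)
        levels.append(_smooth_and_resample(image, grid, factor))
    return levels


# ---------------------------------------------------------------------------
# Histogram matching
# ---------------------------------------------------------------------------


def histogram_match(
    moving: ScalarImage,
    reference: ScalarImage,
    levels: int = 64,
    match_points: int = 7,
) -> ScalarImage:
    """Piecewise-linear intensity remap of ``moving`` onto ``reference``.

    Intensities are histogrammed into ``levels`` bins; the remap sends the
    moving image's quantiles at ``match_points`` interior probabilities onto
    the reference's, interpolating linearly between match points and
    extrapolating linearly at the tails.  The mapping is monotone
    non-decreasing.  Defaults: 64 levels, 7 match points.
    """
    if not (levels >= match_points >= 1):
        raise ValueError("need levels >= match_points >= 1")
    mv = moving.values.ravel()
    rv = reference.values.ravel()
    if np.ptp(mv) == 0:
        warnings.warn("moving image is constant; histogram match is a no-op", stacklevel=2)
        return moving.copy()

    probs = np.arange(1, match_points + 1) / (match_points + 1)
    m_q = _binned_quantiles(mv, probs, levels)
    r_q = _binned_quantiles(rv, probs, levels)
    # enforce monotone targets so the map cannot fold
    r_q = np.maximum.accumulate(r_q)

    uniq = np.unique(m_q)
    if uniq.size < 2:
        warnings.warn("moving quantiles degenerate; histogram match is a no-op", stacklevel=2)
        return moving.copy()
    keep = np.searchsorted(uniq, m_q)
    # collapse duplicate source quantiles, keeping the mean target
    src = uniq
    dst = np.array([r_q[keep == i].mean() for i in range(uniq.size)])

    out = np.interp(moving.values, src, dst)
    # linear extrapolation beyond the outermost match points
    lo_slope = (dst[1] - dst[0]) / (src[1] - src[0])
    hi_slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
    below = moving.values < src[0]
    above = moving.values > src[-1]
    out[below] = dst[0] + lo_slope * (moving.values[below] - src[0])
    out[above] = dst[-1] + hi_slope * (moving.values[above] - src[-1])
    return ScalarImage(moving.grid, out)


def _binned_quantiles(values: np.ndarray, probs: np.ndarray, levels: int) -> np.ndarray:
    """Quantiles computed from a ``levels``-bin histogram CDF."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full(probs.shape, lo)
    hist, edges = np.histogram(values, bins=levels, range=(lo, hi))
    cdf = np.cumsum(hist) / values.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    return np.interp(probs, cdf, centers)


# ---------------------------------------------------------------------------
# Rigid pre-alignment by blockwise local correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidSearchConfig:
    """Settings for the local-correlation rigid search."""

    block_size: int = 16
    variance_threshold: float = 25.0  # HU^2; blocks flatter than this are skipped
    include_rotations: bool = True
    downsample_factor: int = 2
    n_starts: int = 3
    seed: int = 0
    translation_steps_mm: tuple[float, ...] = (4.0, 2.0, 1.0, 0.5, 0.25, 0.125)
    rotation_steps_deg: tuple[float, ...] = (2.0, 1.0, 0.5, 0.25, 0.12, 0.06)
    max_sweeps_per_step: int = 8


def _block_ncc(fixed: np.ndarray, moved: np.ndarray, block: int, var_thresh: float):
    """Mean of blockwise normalized cross-correlations over usable blocks."""
    shape = fixed.shape
    trimmed = tuple((s // block) * block for s in shape)
    if min(trimmed) == 0:
        raise ValueError("image smaller than one block")
    f = fixed[: trimmed[0], : trimmed[1], : trimmed[2]]
    m = moved[: trimmed[0], : trimmed[1], : trimmed[2]]
    nb = tuple(t // block for t in trimmed)
    f = f.reshape(nb[0], block, nb[1], block, nb[2], block)
    m = m.reshape(nb[0], block, nb[1], block, nb[2], block)
    axes = (1, 3, 5)
    fm = f.mean(axis=axes, keepdims=True)
    mm = m.mean(axis=axes, keepdims=True)
    fc = f - fm
    mc = m - mm
    fvar = (fc * fc).mean(axis=axes)
    mvar = (mc * mc).mean(axis=axes)
    usable = fvar > var_thresh
    n_usable = int(usable.sum())
    if n_usable < 3:
        raise ValueError("insufficient structure: fewer than 3 usable blocks")
    cov = (fc * mc).mean(axis=axes)
    denom = np.sqrt(fvar * np.maximum(mvar, 1e-12))
    ncc = np.where(usable, cov / np.maximum(denom, 1e-12), 0.0)
    return float(ncc[usable].mean()), n_usable


def rigid_local_correlation(
    fixed: ScalarImage,
    moving: ScalarImage,
    config: RigidSearchConfig | None = None,
) -> RigidTransform:
    """Rigid transform maximizing mean blockwise NCC between ``fixed`` and
    the rigidly warped ``moving``.

    The 6 parameters (3 translations mm, 3 rotations deg about the fixed
    image centre) are optimized by seeded multi-start coordinate descent
    with a shrinking step schedule; accepted steps never decrease the
    objective (the trace is available on the returned transform as
    ``.objective_trace``).
    """
    cfg = config or RigidSearchConfig()
    # evaluate on a decimated grid for speed; parameters stay in world mm/deg
    step = max(1, cfg.downsample_factor)
    f_vals = fixed.values[::step, ::step, ::step]
    eval_grid = ImageGrid(
        f_vals.shape,
        tuple(s * step for s in fixed.grid.spacing),
        fixed.grid.origin,
    )
    centers = eval_grid.voxel_centers()
    center = fixed.grid.world_center()
    fill = float(moving.values.min())
    block = max(4, cfg.block_size // step)
    trace: list[float] = []

    def objective(params) -> float:
        tr = RigidTransform.from_params(params[:3], params[3:], center)
        moved = trilinear_sample(moving, tr.apply(centers.reshape(-1, 3)), fill)
        moved = moved.reshape(f_vals.shape)
        score, _ = _block_ncc(f_vals, moved, block, cfg.variance_threshold)
        return score

    rng = np.random.default_rng(cfg.seed)
    starts = [np.zeros(6)]
    for _ in range(max(0, cfg.n_starts - 1)):
        perturb = np.concatenate([rng.uniform(-5, 5, 3), rng.uniform(-2, 2, 3)])
        if not cfg.include_rotations:
            perturb[3:] = 0.0
        starts.append(perturb)

    n_params = 6 if cfg.include_rotations else 3
    best_params, best_score = None, -np.inf
    for start in starts:
        params = start.copy()
        score = objective(params)
        for t_step, r_step in zip(cfg.translation_steps_mm, cfg.rotation_steps_deg):
            steps = np.array([t_step] * 3 + [r_step] * 3)
            for _ in range(cfg.max_sweeps_per_step):
                improved = False
                for p in range(n_params):
                    for sign in (+1.0, -1.0):
                        cand = params.copy()
                        cand[p] += sign * steps[p]
                        cand_score = objective(cand)
                        if cand_score > score + 1e-12:
                            params, score = cand, cand_score
                            trace.append(score)
                            improved = True
                if not improved:
                    break
        if score > best_score:
            best_params, best_score = params, score

    result = RigidTransform.from_params(best_params[:3], best_params[3:], center)
    result.objective_trace = trace  # type: ignore[attr-defined]
    result.objective_value = best_score  # type: ignore[attr-defined]
    return result
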