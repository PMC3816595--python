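"""Salient-feature-based registration.

Interest points are scale-space blob extrema (scale-normalized
Laplacian-of-Gaussian over a scale ladder, both polarities) refined to
subvoxel positions; each feature carries a z-scored local intensity patch
sampled at its scale as descriptor.
Correspondences come from mutual-nearest-neighbour descriptor matching
gated by a spatial displacement limit and a distance-ratio test, and are
interpolated by a 3-D thin-plate spline (biharmonic kernel ``U(r) = r``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .image_model import DisplacementField, ImageGrid, ScalarImage, trilinear_sample

__all__ = [
    "SalientFeature",
    "FeatureConfig",
    "MatchConfig",
    "TPSTransform",
    "detect_salient_features",
    "match_features",
    "fit_tps",
    "evaluate_tps",
    "sfbr_register",
]


@dataclass
class SalientFeature:
    """A detected interest point: centre (world mm), scale (mm), descriptor."""

    center: np.ndarray
    scale: float
    strength: float
    descriptor: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.descriptor = np.asarray(self.descriptor, dtype=float)
        if self.scale <= 0:
            raise ValueError("feature scale must be positive")
        if not np.all(np.isfinite(self.descriptor)):
            raise ValueError("descriptor must be finite")


@dataclass(frozen=True)
class FeatureConfig:
    """Scale-space blob detection settings.

    ``sigmas_mm`` is the detection-scale ladder; the reported feature scale
    is ``sqrt(3) * sigma`` (the radius of the binary sphere whose LoG
    response peaks at that sigma).  Extrema are refined to subvoxel
    positions by a quadratic fit, detections within ``border_margin_mm`` of
    the volume faces are discarded (structures cut by the field of view do
    not move with the anatomy), and ``max_features`` caps the output at the
    strongest responses.
    """

    sigmas_mm: tuple[float, ...] = (9.0, 13.5, 20.0, 30.0)
    threshold: float = 12.0  # min |scale-normalized LoG| response
    min_spacing_mm: float = 8.0
    border_margin_mm: float = 12.0
    max_features: int = 2000
    descriptor_samples: int = 5  # samples per axis of the descriptor patch
    descriptor_radius_scales: float = 1.5  # patch radius in units of sigma


@dataclass(frozen=True)
class MatchConfig:
    max_displacement_mm: float = 30.0
    ratio_test: float = 0.8


def _scale_normalized_log(values: np.ndarray, sigma_vox) -> np.ndarray:
    sigma_mean = float(np.mean(sigma_vox))
    return -(sigma_mean**2) * ndimage.gaussian_laplace(values, sigma_vox, mode="nearest")


def _refine_subvoxel(response: np.ndarray, x: int, y: int, z: int) -> np.ndarray:
    """Quadratic-fit offset (voxels, clamped to +/-1) of a discrete extremum."""
    g = response
    dims = g.shape
    if min(x, y, z) < 1 or x >= dims[0] - 1 or y >= dims[1] - 1 or z >= dims[2] - 1:
        return np.zeros(3)
    grad = 0.5 * np.array(
        [
            g[x + 1, y, z] - g[x - 1, y, z],
            g[x, y + 1, z] - g[x, y - 1, z],
            g[x, y, z + 1] - g[x, y, z - 1],
        ]
    )
    hess = np.empty((3, 3))
    hess[0, 0] = g[x + 1, y, z] - 2 * g[x, y, z] + g[x - 1, y, z]
    hess[1, 1] = g[x, y + 1, z] - 2 * g[x, y, z] + g[x, y - 1, z]
    hess[2, 2] = g[x, y, z + 1] - 2 * g[x, y, z] + g[x, y, z - 1]
    hess[0, 1] = hess[1, 0] = 0.25 * (
        g[x + 1, y + 1, z] - g[x + 1, y - 1, z] - g[x - 1, y + 1, z] + g[x - 1, y - 1, z]
    )
    hess[0, 2] = hess[2, 0] = 0.25 * (
        g[x + 1, y, z + 1] - g[x + 1, y, z - 1] - g[x - 1, y, z + 1] + g[x - 1, y, z - 1]
    )
    hess[1, 2] = hess[2, 1] = 0.25 * (
        g[x, y + 1, z + 1] - g[x, y + 1, z - 1] - g[x, y - 1, z + 1] + g[x, y - 1, z - 1]
    )
    try:
        offset = -np.linalg.solve(hess, grad)
    except np.linalg.LinAlgError:
        return np.zeros(3)
    return np.clip(offset, -1.0, 1.0)


def detect_salient_features(
    image: ScalarImage, config: FeatureConfig | None = None
) -> list[SalientFeature]:
    """Scale-space blob detection with non-maximum suppression.

    Local extrema of the scale-normalized LoG (bright and dark blobs) over
    space and scale are kept if their absolute response exceeds the
    threshold, refined to subvoxel positions, thinned to a minimum spacing,
    and capped at the strongest ``max_features``.  Deterministic; a
    constant image yields no features.
    """
    cfg = config or FeatureConfig()
    sp = np.asarray(image.grid.spacing)
    if np.ptp(image.values) == 0:
        return []
    stack = np.stack(
        [_scale_normalized_log(image.values, sigma / sp) for sigma in cfg.sigmas_mm]
    )
    footprint = np.ones((3, 3, 3, 3), dtype=bool)
    maxima = (stack == ndimage.maximum_filter(stack, footprint=footprint, mode="nearest")) & (
        stack > cfg.threshold
    )
    minima = (stack == ndimage.minimum_filter(stack, footprint=footprint, mode="nearest")) & (
        stack < -cfg.threshold
    )
    cand = np.argwhere(maxima | minima)
    if cand.size == 0:
        return []
    strengths = np.abs(stack[tuple(cand.T)])
    order = np.argsort(-strengths, kind="stable")
    cand = cand[order]
    strengths = strengths[order]

    origin = np.asarray(image.grid.origin)
    extent = origin + (np.asarray(image.grid.dims) - 1) * sp
    kept: list[tuple[np.ndarray, float, float]] = []
    kept_pts: list[np.ndarray] = []
    min_sq = cfg.min_spacing_mm**2
    for row, strength in zip(cand, strengths):
        sigma = cfg.sigmas_mm[row[0]]
        offset = _refine_subvoxel(stack[row[0]], *row[1:])
        center = image.grid.index_to_world(row[1:] + offset)
        if np.any(center - origin < cfg.border_margin_mm) or np.any(
            extent - center < cfg.border_margin_mm
        ):
            continue
        if kept_pts:
            d = np.asarray(kept_pts) - center
            if np.min((d * d).sum(axis=1)) < min_sq:
                continue
        kept_pts.append(center)
        kept.append((center, sigma, float(strength)))
        if len(kept) >= cfg.max_features:
            break

    offsets = _descriptor_offsets(cfg.descriptor_samples)
    features = []
    for center, sigma, strength in kept:
        descriptor = _patch_descriptor(image, center, sigma, offsets, cfg)
        features.append(
            SalientFeature(center, float(np.sqrt(3.0) * sigma), strength, descriptor)
        )
    return features


def _descriptor_offsets(n: int) -> np.ndarray:
    lin = np.linspace(-1.0, 1.0, n)
    return np.stack(np.meshgrid(lin, lin, lin, indexing="ij"), axis=-1).reshape(-1, 3)


def _patch_descriptor(
    image: ScalarImage,
    center: np.ndarray,
    sigma: float,
    offsets: np.ndarray,
    cfg: FeatureConfig,
) -> np.ndarray:
    """Z-scored intensity patch sampled at the feature's scale.

    Invariant to affine intensity changes and discriminative enough to
    disambiguate positions along smooth organ boundaries.
    """
    pts = center + offsets * (cfg.descriptor_radius_scales * sigma)
    values = trilinear_sample(image, pts)
    std = values.std()
    return (values - values.mean()) / (std if std > 0 else 1.0)


@dataclass
class Correspondences:
    """One-to-one matched feature locations (world mm)."""

    fixed_points: np.ndarray
    moving_points: np.ndarray
    fixed_indices: np.ndarray
    moving_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.fixed_points)


def match_features(
    fixed_feats: list[SalientFeature],
    moving_feats: list[SalientFeature],
    config: MatchConfig | None = None,
) -> Correspondences:
    """Mutual-nearest-neighbour descriptor matching with spatial gating.

    Candidate pairs must lie within ``max_displacement_mm`` of each other
    (post rigid alignment) and pass the nearest/second-nearest descriptor
    distance ratio test; matches must be mutual.  Raises if no
    correspondence survives.
    """
    cfg = config or MatchConfig()
    if not fixed_feats or not moving_feats:
        raise ValueError("feature lists must be non-empty")
    fp = np.array([f.center for f in fixed_feats])
    mp = np.array([f.center for f in moving_feats])
    fd = np.array([f.descriptor for f in fixed_feats])
    md = np.array([f.descriptor for f in moving_feats])
    spatial = cdist(fp, mp)
    desc = cdist(fd, md)
    desc = np.where(spatial <= cfg.max_displacement_mm, desc, np.inf)

    pairs = []
    for i in range(len(fixed_feats)):
        row = desc[i]
        j = int(np.argmin(row))
        if not np.isfinite(row[j]):
            continue
        second = np.partition(row, 1)[1] if len(row) > 1 else np.inf
        threshold = cfg.ratio_test * second  # inf * ratio -> inf keeps lone candidates
        if not np.isfinite(second):
            threshold = np.inf if cfg.ratio_test > 0 else 0.0
        if row[j] >= threshold:
            continue
        back = int(np.argmin(desc[:, j]))
        if back != i:
            continue
        pairs.append((i, j))
    if not pairs:
        raise ValueError("no correspondences survived matching")
    fi = np.array([p[0] for p in pairs])
    mi = np.array([p[1] for p in pairs])
    return Correspondences(fp[fi], mp[mi], fi, mi)


# ---------------------------------------------------------------------------
# Thin-plate splines (3-D biharmonic kernel U(r) = r)
# ---------------------------------------------------------------------------


@dataclass
class TPSTransform:
    """3-D thin-plate spline mapping source-frame points to target-frame points.

    ``direction`` documents which way the map goes ("fixed_to_moving" for
    DVF-style pull-back use, "moving_to_fixed" for mesh propagation);
    consumers validate it.  Weights satisfy the orthogonality
    side-conditions (zero sum and first moments) within 1e-8.
    """

    source_landmarks: np.ndarray
    target_landmarks: np.ndarray
    affine: np.ndarray  # 4x3: rows [constant; x; y; z] per output axis
    weights: np.ndarray  # n x 3 kernel weights
    regularization: float = 0.0
    direction: str = "fixed_to_moving"
    condition_number: float = float("nan")

    def bending_energy(self) -> float:
        """Non-negative bending energy; zero iff the map is affine.

        Uses the conditionally-positive-definite kernel ``-r`` so the
        quadratic form is non-negative on moment-free weights.
        """
        k = cdist(self.source_landmarks, self.source_landmarks)
        return float(max(0.0, -np.einsum("ia,ij,ja->", self.weights, k, self.weights)))


def fit_tps(
    source_points: np.ndarray,
    target_points: np.ndarray,
    regularization: float = 0.01,
    direction: str = "fixed_to_moving",
) -> TPSTransform:
    """Fit a 3-D TPS through landmark correspondences.

    Solves the standard bordered system with kernel ``U(r) = r`` and ridge
    ``regularization`` (mm) added to the kernel diagonal; zero
    regularization interpolates the landmarks exactly.  Requires at least 5
    non-coplanar correspondences.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    dst = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ValueError("source and target point lists must match")
    n = len(src)
    if n < 5:
        raise ValueError("need at least 5 correspondences")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    p = np.hstack([np.ones((n, 1)), src])
    if np.linalg.matrix_rank(p, tol=1e-8 * max(1.0, np.abs(src).max())) < 4:
        raise ValueError(
            "degenerate landmark set: source points are coplanar or collinear"
        )
    # solve in the conditionally-positive-definite convention (kernel -r) so
    # the ridge genuinely penalizes bending energy; evaluation uses U(r) = r,
    # which only flips the sign of the stored kernel weights
    k = -cdist(src, src) + regularization * np.eye(n)
    system = np.zeros((n + 4, n + 4))
    system[:n, :n] = k
    system[:n, n:] = p
    system[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = dst
    try:
        solution = np.linalg.solve(system, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate landmark set: {exc}") from exc
    cond = float(np.linalg.cond(system)) if n <= 600 else float("nan")
    return TPSTransform(
        source_landmarks=src,
        target_landmarks=dst,
        affine=solution[n:],
        weights=-solution[:n],
        regularization=regularization,
        direction=direction,
        condition_number=cond,
    )


def evaluate_tps(tps: TPSTransform, points: np.ndarray) -> np.ndarray:
    """Map points through the spline: ``U(dist) @ W + [1, p] @ A``."""
    pts = np.asarray(points, dtype=float)
    flat = pts.reshape(-1, 3)
    u = cdist(flat, tps.source_landmarks)
    out = u @ tps.weights + np.hstack([np.ones((len(flat), 1)), flat]) @ tps.affine
    return out.reshape(pts.shape)


def tps_to_field(tps: TPSTransform, grid: ImageGrid, chunk: int = 200_000) -> DisplacementField:
    """Sample a fixed->moving TPS as a pull-back displacement field."""
    if tps.direction != "fixed_to_moving":
        raise ValueError("field sampling needs a fixed_to_moving transform")
    centers = grid.voxel_centers().reshape(-1, 3)
    vectors = np.empty_like(centers)
    for start in range(0, len(centers), chunk):
        block = centers[start : start + chunk]
        vectors[start : start + chunk] = evaluate_tps(tps, block) - block
    return DisplacementField(grid, vectors.reshape(grid.dims + (3,)))


@dataclass
class SFBRResult:
    """Both directed TPS maps plus the matched correspondences."""

    tps_fixed_to_moving: TPSTransform
    tps_moving_to_fixed: TPSTransform
    correspondences: Correspondences
    fixed_features: list
    moving_features: list


def sfbr_register(
    fixed: ScalarImage,
    moving: ScalarImage,
    feature_config: FeatureConfig | None = None,
    match_config: MatchConfig | None = None,
    regularization: float = 0.01,
) -> SFBRResult:
    """Detect, match and fit thin-plate splines in both directions.

    The fixed->moving spline supports DVF-style mask pull-back; the
    moving->fixed spline (fitted on the reversed correspondences) is the
    one used for mesh-vertex propagation.
    """
    ff = detect_salient_features(fixed, feature_config)
    mf = detect_salient_features(moving, feature_config)
    corr = match_features(ff, mf, match_config)
    f2m = fit_tps(corr.fixed_points, corr.moving_points, regularization, "fixed_to_moving")
    m2f = fit_tps(corr.moving_points, corr.fixed_points, regularization, "moving_to_fixed")
    return SFBRResult(f2m, m2f, corr, ff, mf)
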