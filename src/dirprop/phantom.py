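"""Synthetic thorax phantom with ground-truth deformations.

Generates pre/mid image pairs on a CT-like grid: two low-density lungs, a
high-contrast tumour sphere, a spinal cord inside a vertebral annulus, a
low-contrast esophagus tube and a low-contrast nodal sphere, all embedded in
a soft-tissue body ellipse over an air background.

The mid-treatment image and masks are produced by *re-rasterizing* the
analytically deformed geometry — not by resampling the pre image — so the
ground truth carries no interpolation bias from the code under test.
Ground-truth fields are emitted in the fixed-frame pull-back convention:
the vector at mid-treatment voxel ``x`` points to the corresponding
pre-treatment location ``x + u(x)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image_model import DisplacementField, ImageGrid, ROIMask, ScalarImage

__all__ = [
    "PhantomSpec",
    "GroundTruthDeformation",
    "translation_deformation",
    "gaussian_bump_deformation",
    "radial_scale_deformation",
    "composite_deformation",
    "make_phantom",
    "make_deformed_pair",
    "generate_cohort",
    "DeformedPair",
]

AIR_HU = -1000.0


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def inside(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d * d).sum(axis=-1) <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def inside(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        return (d * d).sum(axis=-1) <= self.radius**2


@dataclass(frozen=True)
class ZCylinder:
    """Axial tube: annulus ``r_inner <= r_xy <= r_outer`` over a z range."""

    center_xy: tuple[float, float]
    r_outer: float
    r_inner: float = 0.0
    z_range: tuple[float, float] | None = None

    def inside(self, pts: np.ndarray) -> np.ndarray:
        d = pts[..., :2] - np.asarray(self.center_xy)
        r2 = (d * d).sum(axis=-1)
        ok = (r2 <= self.r_outer**2) & (r2 >= self.r_inner**2)
        if self.z_range is not None:
            ok &= (pts[..., 2] >= self.z_range[0]) & (pts[..., 2] <= self.z_range[1])
        return ok


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of the synthetic thorax.

    Default grid is 128 x 128 x 48 voxels at 2 x 2 x 3 mm (origin 0), i.e. a
    256 x 256 x 144 mm field of view.  All organ coordinates are world mm.
    """

    grid: ImageGrid = ImageGrid((128, 128, 48), (2.0, 2.0, 3.0))
    body: Ellipsoid = Ellipsoid((127.0, 127.0, 70.5), (112.0, 85.0, 400.0))
    body_hu: float = 0.0
    lung_left: Ellipsoid = Ellipsoid((75.0, 115.0, 70.0), (42.0, 52.0, 58.0))
    lung_right: Ellipsoid = Ellipsoid((179.0, 115.0, 70.0), (42.0, 52.0, 58.0))
    lung_hu: float = -750.0
    tumour: Sphere = Sphere((170.0, 105.0, 72.0), 15.0)
    tumour_hu: float = 40.0
    vertebra: ZCylinder = ZCylinder((127.0, 190.0), 14.0, 6.0)
    vertebra_hu: float = 700.0
    cord: ZCylinder = ZCylinder((127.0, 190.0), 4.5)
    cord_hu: float = 60.0
    esophagus: ZCylinder = ZCylinder((127.0, 165.0), 5.0)
    esophagus_hu: float = 15.0
    node: Sphere = Sphere((127.0, 140.0, 80.0), 9.0)
    node_hu: float = 20.0
    # anatomical texture: seeded Gaussian blobs emulating vessels / bronchi /
    # chest-wall structure; part of the geometry, so they deform with it and
    # give the feature detector distinctive structure to anchor on.  Blobs
    # may straddle the body wall (extent fraction > 1) so the wall itself is
    # not tangentially featureless.
    texture_n_blobs: int = 400
    texture_amplitude_hu: float = 80.0
    texture_sigma_range_mm: tuple[float, float] = (5.0, 16.0)
    texture_extent_frac: float = 1.05
    noise_sigma_hu: float = 8.0
    seed: int = 0

    def roi_shapes(self) -> dict:
        return {
            "GTV": self.tumour,
            "nodal-GTV": self.node,
            "lung-L": self.lung_left,
            "lung-R": self.lung_right,
            "esophagus": self.esophagus,
            "cord": self.cord,
        }

    def validate(self) -> None:
        """Cheap containment checks: organs inside body, tumour near a lung."""
        for label, shape in self.roi_shapes().items():
            if isinstance(shape, (Sphere, Ellipsoid)):
                c = np.asarray(shape.center)
            else:
                c = np.array([*shape.center_xy, self.body.center[2]])
            if not self.body.inside(c[None, :])[0]:
                raise ValueError(f"organ '{label}' centre lies outside the body")
        tc = np.asarray(self.tumour.center)[None, :]
        near_lung = (
            self.lung_left.inside(tc)[0] or self.lung_right.inside(tc)[0]
        )
        if not near_lung:
            raise ValueError("tumour must sit inside or abut a lung")

    def texture_blobs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Seeded texture-blob parameters (centres, sigmas, amplitudes)."""
        rng = np.random.default_rng(self.seed * 7919 + 17)
        n = self.texture_n_blobs
        bc = np.asarray(self.body.center)
        ba = np.asarray(self.body.semi_axes)
        zspan = (self.grid.dims[2] - 1) * self.grid.spacing[2]
        f = self.texture_extent_frac
        centers = np.empty((n, 3))
        centers[:, 0] = bc[0] + rng.uniform(-f, f, n) * ba[0]
        centers[:, 1] = bc[1] + rng.uniform(-f, f, n) * ba[1]
        centers[:, 2] = rng.uniform(0.0, zspan, n)
        sigmas = rng.uniform(*self.texture_sigma_range_mm, n)
        amplitudes = rng.uniform(-1.0, 1.0, n) * self.texture_amplitude_hu
        return centers, sigmas, amplitudes

    def analytic_hu(self, pts: np.ndarray) -> np.ndarray:
        """Noise-free HU at arbitrary world points (priority rasterization)."""
        pts = np.asarray(pts, dtype=float)
        hu = np.full(pts.shape[:-1], AIR_HU)
        hu[self.body.inside(pts)] = self.body_hu
        hu[self.lung_left.inside(pts)] = self.lung_hu
        hu[self.lung_right.inside(pts)] = self.lung_hu
        hu[self.vertebra.inside(pts)] = self.vertebra_hu
        hu[self.cord.inside(pts)] = self.cord_hu
        hu[self.esophagus.inside(pts)] = self.esophagus_hu
        hu[self.node.inside(pts)] = self.node_hu
        hu[self.tumour.inside(pts)] = self.tumour_hu
        if self.texture_n_blobs > 0 and self.texture_amplitude_hu != 0:
            from scipy.spatial import cKDTree

            centers, sigmas, amplitudes = self.texture_blobs()
            flat = pts.reshape(-1, 3)
            acc = np.zeros(len(flat))
            tree = cKDTree(flat)
            for c, s, a in zip(centers, sigmas, amplitudes):
                near = tree.query_ball_point(c, 3.5 * s, return_sorted=False)
                if not near:
                    continue
                near = np.asarray(near, dtype=np.intp)
                d2 = ((flat[near] - c) ** 2).sum(axis=1)
                acc[near] += a * np.exp(-d2 / (2.0 * s * s))
            texture = acc.reshape(pts.shape[:-1])
            hu = hu + np.where(self.body.inside(pts), texture, 0.0)
        return hu


# ---------------------------------------------------------------------------
# Ground-truth deformations (analytic maps from the mid frame to the pre frame)
# ---------------------------------------------------------------------------


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass(frozen=True)
class GroundTruthDeformation:
    """Analytic displacement ``u`` with ``pre_point = mid_point + u(mid_point)``.

    ``kind`` is one of translation / gaussian_bump / radial_scale /
    composite; parts hold the parameter tuples needed by
    :meth:`displacement`.
    """

    kind: str
    parts: tuple = ()

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        u = np.zeros_like(pts)
        for part in self.parts:
            u += _part_displacement(part, pts)
        return u

    def field(self, grid: ImageGrid, check_jacobian: bool = True) -> DisplacementField:
        """Sample the analytic displacement at voxel centres.

        With ``check_jacobian`` the discrete Jacobian determinant of the map
        ``x + u(x)`` is asserted positive everywhere (no folding).
        """
        centers = grid.voxel_centers()
        vectors = self.displacement(centers)
        dvf = DisplacementField(grid, vectors)
        if check_jacobian:
            det = _jacobian_determinant(dvf)
            if det.min() <= 0:
                raise ValueError(
                    f"deformation folds: min Jacobian determinant {det.min():.4f}"
                )
        return dvf


def _part_displacement(part: tuple, pts: np.ndarray) -> np.ndarray:
    kind = part[0]
    if kind == "translation":
        (_, shift) = part
        return np.broadcast_to(np.asarray(shift, dtype=float), pts.shape).copy()
    if kind == "gaussian_bump":
        (_, amplitude, center, sigma) = part
        d = pts - np.asarray(center)
        w = np.exp(-(d * d).sum(axis=-1) / (2.0 * sigma**2))
        return w[..., None] * np.asarray(amplitude, dtype=float)
    if kind == "radial_scale":
        (_, center, scale, r_core, r_blend) = part
        d = pts - np.asarray(center)
        rho = np.sqrt((d * d).sum(axis=-1))
        # radial profile h(rho) = rho/scale inside the core, -> rho beyond the
        # blend radius; the displacement magnitude is h(rho) - rho
        w = _smoothstep((rho - r_core) / max(r_blend - r_core, 1e-9))
        h = (1.0 - w) * rho / scale + w * rho
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = np.where(rho > 1e-12, h / np.maximum(rho, 1e-12) - 1.0, 1.0 / scale - 1.0)
        return gain[..., None] * d
    raise ValueError(f"unknown deformation part kind: {kind}")


def translation_deformation(shift_mm) -> GroundTruthDeformation:
    return GroundTruthDeformation("translation", (("translation", tuple(shift_mm)),))


def gaussian_bump_deformation(amplitude_mm, center_mm, sigma_mm) -> GroundTruthDeformation:
    return GroundTruthDeformation(
        "gaussian_bump",
        (("gaussian_bump", tuple(amplitude_mm), tuple(center_mm), float(sigma_mm)),),
    )


def radial_scale_deformation(
    center_mm, linear_scale: float, r_core_mm: float, r_blend_mm: float
) -> GroundTruthDeformation:
    """Exact linear rescale by ``linear_scale`` inside ``r_core_mm``.

    A mid-frame shape boundary at radius ``r`` maps to a pre-frame boundary
    at ``r / linear_scale`` as long as both stay inside the core, so a pre
    tumour of radius R becomes a mid tumour of radius ``linear_scale * R``
    (volume ratio ``linear_scale**3``) exactly.
    """
    if linear_scale <= 0:
        raise ValueError("linear_scale must be positive")
    if r_blend_mm <= r_core_mm:
        raise ValueError("r_blend_mm must exceed r_core_mm")
    return GroundTruthDeformation(
        "radial_scale",
        (("radial_scale", tuple(center_mm), float(linear_scale), float(r_core_mm), float(r_blend_mm)),),
    )


def composite_deformation(*deformations: GroundTruthDeformation) -> GroundTruthDeformation:
    parts: tuple = ()
    for d in deformations:
        parts = parts + d.parts
    return GroundTruthDeformation("composite", parts)


def _jacobian_determinant(dvf: DisplacementField) -> np.ndarray:
    """Discrete Jacobian determinant of ``x -> x + u(x)`` at every voxel."""
    sp = dvf.grid.spacing
    jac = np.empty(dvf.grid.dims + (3, 3))
    for comp in range(3):
        grads = np.gradient(dvf.vectors[..., comp], *sp)
        for axis in range(3):
            jac[..., comp, axis] = grads[axis]
    jac += np.eye(3)
    return np.linalg.det(jac)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def make_phantom(spec: PhantomSpec) -> tuple[ScalarImage, dict]:
    """Rasterize the phantom: noisy image plus exact (noise-free) ROI masks."""
    spec.validate()
    centers = spec.grid.voxel_centers()
    hu = spec.analytic_hu(centers)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma_hu, size=hu.shape)
    image = ScalarImage(spec.grid, hu)
    masks = {
        name: ROIMask(spec.grid, shape.inside(centers), name)
        for name, shape in spec.roi_shapes().items()
    }
    return image, masks


@dataclass
class DeformedPair:
    """A pre/mid phantom pair with its ground-truth pull-back field."""

    spec: PhantomSpec
    deformation: GroundTruthDeformation
    pre_image: ScalarImage
    pre_masks: dict
    mid_image: ScalarImage
    mid_masks: dict
    true_field: DisplacementField


def make_deformed_pair(
    spec: PhantomSpec, deformation: GroundTruthDeformation
) -> DeformedPair:
    """Build the pre phantom and the analytically deformed mid phantom.

    Mid voxels are filled by evaluating the analytic geometry at
    ``x + u(x)`` (re-rasterization); mid noise uses an independent stream
    derived from ``spec.seed``.
    """
    pre_image, pre_masks = make_phantom(spec)
    true_field = deformation.field(spec.grid, check_jacobian=True)
    centers = spec.grid.voxel_centers()
    pulled = centers + true_field.vectors
    mid_hu = spec.analytic_hu(pulled)
    rng = np.random.default_rng(spec.seed + 10_000)
    if spec.noise_sigma_hu > 0:
        mid_hu = mid_hu + rng.normal(0.0, spec.noise_sigma_hu, size=mid_hu.shape)
    mid_image = ScalarImage(spec.grid, mid_hu)
    mid_masks = {
        name: ROIMask(spec.grid, shape.inside(pulled), name)
        for name, shape in spec.roi_shapes().items()
    }
    return DeformedPair(
        spec, deformation, pre_image, pre_masks, mid_image, mid_masks, true_field
    )


def tumour_shrink_deformation(
    spec: PhantomSpec, volume_change_fraction: float
) -> GroundTruthDeformation:
    """Radial deformation changing the tumour volume by the given fraction.

    ``volume_change_fraction`` is ``(pre - mid) / pre``; positive values
    shrink the tumour.  The linear scale is the cube root of the volume
    ratio; the exact-scale core covers the tumour in both frames.
    """
    if volume_change_fraction >= 1.0:
        raise ValueError("volume cannot shrink by 100% or more")
    linear_scale = float((1.0 - volume_change_fraction) ** (1.0 / 3.0))
    r = spec.tumour.radius
    r_core = max(r, linear_scale * r) + 4.0
    r_blend = r_core + 28.0
    return radial_scale_deformation(spec.tumour.center, linear_scale, r_core, r_blend)


def generate_cohort(
    n: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    shrink_fraction: float = 14.0 / 17.0,
) -> tuple[list[DeformedPair], pd.DataFrame]:
    """Seeded cohort of deformed pairs with a per-case manifest.

    Roughly ``shrink_fraction`` of cases shrink (volume change drawn from
    1-30%) and the rest grow by more than 10%, echoing the sign pattern of
    a longitudinal lung cohort.  The manifest carries per-case tumour
    volumes (analytic and rasterized) ready for volume-change tabulation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    n_shrink = int(round(shrink_fraction * n))
    changes = np.concatenate(
        [
            rng.uniform(0.01, 0.30, size=n_shrink),
            rng.uniform(-0.30, -0.103, size=n - n_shrink),
        ]
    )
    rng.shuffle(changes)
    pairs: list[DeformedPair] = []
    rows = []
    for case, change in enumerate(changes, start=1):
        spec = replace(base_spec, seed=seed + 131 * case)
        deformation = tumour_shrink_deformation(spec, float(change))
        pair = make_deformed_pair(spec, deformation)
        pairs.append(pair)
        r = spec.tumour.radius
        scale = (1.0 - change) ** (1.0 / 3.0)
        rows.append(
            {
                "case": case,
                "requested_volume_change_fraction": float(change),
                "linear_scale": float(scale),
                "analytic_pre_cm3": 4.0 / 3.0 * np.pi * r**3 / 1000.0,
                "analytic_mid_cm3": 4.0 / 3.0 * np.pi * (scale * r) ** 3 / 1000.0,
                "raster_pre_cm3": pair.pre_masks["GTV"].volume_cm3(),
                "raster_mid_cm3": pair.mid_masks["GTV"].volume_cm3(),
            }
        )
    manifest = pd.DataFrame(rows)
    return pairs, manifest
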