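"""Core geometric data model: grids, images, displacement fields, masks, meshes.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based; the world coordinate (mm) of voxel ``(i, j, k)``
  is ``origin + index * spacing``.  Axis 2 (the third axis) is the axial /
  slice axis used by the slicewise metrics.
* Displacement fields live on the *fixed* image grid and use the pull-back
  convention: the vector stored at fixed voxel centre ``x`` points to the
  corresponding location ``x + u(x)`` in the moving image.
* Array layout is ``(nx, ny, nz)`` (index order matches the grid dims);
  displacement fields are ``(nx, ny, nz, 3)`` with mm components on world
  axes.
* Out-of-grid sampling returns a fill value (default: the minimum image
  value, air-like for CT) rather than raising.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "ScalarImage",
    "DisplacementField",
    "RigidTransform",
    "ROIMask",
    "ContourMesh",
    "trilinear_sample",
    "warp_pullback",
    "resample_to_grid",
    "resample_field_to_grid",
    "downsample_field",
    "upsample_field",
]


def _as_triple(value, dtype):
    out = tuple(dtype(v) for v in value)
    if len(out) != 3:
        raise ValueError(f"expected a length-3 sequence, got {value!r}")
    return out


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3-D sampling grid in world (mm) coordinates."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "dims", _as_triple(self.dims, int))
        object.__setattr__(self, "spacing", _as_triple(self.spacing, float))
        object.__setattr__(self, "origin", _as_triple(self.origin, float))
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        if not all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world mm points."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """All voxel centre world coordinates as an (nx, ny, nz, 3) array."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a])
            for a in range(3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)

    def world_center(self) -> np.ndarray:
        return self.index_to_world((np.asarray(self.dims) - 1) / 2.0)


@dataclass
class ScalarImage:
    """A scalar-valued volume (HU for CT) on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"value shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    def copy(self) -> "ScalarImage":
        return ScalarImage(self.grid, self.values.copy())


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm, world axes) on the fixed grid.

    Pull-back convention: the vector at fixed voxel ``x`` points to the
    corresponding moving-image location ``x + u(x)``.
    """

    grid: ImageGrid
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        expected = self.grid.dims + (3,)
        if self.vectors.shape != expected:
            raise ValueError(
                f"vector shape {self.vectors.shape} does not match {expected}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must be finite")

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "DisplacementField":
        return cls(grid, np.zeros(grid.dims + (3,)))

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.grid, self.vectors.copy())


@dataclass
class RigidTransform:
    """Rigid map ``x -> R @ x + t`` of world points (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must have determinant +1")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_params(
        cls, translation_mm, angles_deg, center=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Build from translation and XYZ Euler angles, rotating about ``center``."""
        ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        rot = rz @ ry @ rx
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation_mm, dtype=float) + c - rot @ c
        return cls(rot, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``x -> self(other(x))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class ROIMask:
    """Binary region-of-interest mask on an :class:`ImageGrid`."""

    grid: ImageGrid
    labels: np.ndarray
    name: str = "ROI"

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.dims:
            raise ValueError(
                f"label shape {labels.shape} does not match grid dims {self.grid.dims}"
            )
        uniq = np.unique(labels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask labels must be binary (0/1)")
        self.labels = labels.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.labels))

    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    def volume_cm3(self) -> float:
        return self.volume_mm3() / 1000.0

    def centroid_mm(self) -> np.ndarray:
        if self.n_voxels == 0:
            raise ValueError(f"ROI '{self.name}' is empty")
        idx = np.argwhere(self.labels).mean(axis=0)
        return self.grid.index_to_world(idx)

    def copy(self) -> "ROIMask":
        return ROIMask(self.grid, self.labels.copy(), self.name)


@dataclass
class ContourMesh:
    """Closed triangle surface in world mm coordinates."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "ROI"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices must be finite")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        _, counts = np.unique(self.edges(), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def volume_mm3(self) -> float:
        """Enclosed volume via the divergence theorem (orientation-robust)."""
        v0 = self.vertices[self.faces[:, 0]]
        v1 = self.vertices[self.faces[:, 1]]
        v2 = self.vertices[self.faces[:, 2]]
        signed = np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0
        return float(abs(signed))

    def copy(self) -> "ContourMesh":
        return ContourMesh(self.vertices.copy(), self.faces.copy(), self.name)


# ---------------------------------------------------------------------------
# Sampling and warping
# ---------------------------------------------------------------------------


def snap_near_integer_coords(idx: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Snap voxel coordinates within ``tol`` of an integer onto it.

    Guards boundary voxels: a displacement of a few float ulps must not push
    an exact voxel-centre sample outside the grid (where it would pick up
    the fill value instead of the voxel value).
    """
    snapped = np.rint(idx)
    return np.where(np.abs(idx - snapped) < tol, snapped, idx)


def trilinear_sample(
    image: ScalarImage, points: np.ndarray, fill_value: float | None = None
) -> np.ndarray:
    """Trilinearly interpolate ``image`` at world mm ``points``.

    ``points`` may have any leading shape ``(..., 3)``; the result has the
    leading shape.  Points outside the voxel-centre hull of the grid return
    ``fill_value`` (default: the minimum image value).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError("points must have a trailing dimension of 3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    if fill_value is None:
        fill_value = float(image.values.min())
    idx = snap_near_integer_coords(image.grid.world_to_index(pts))
    coords = np.moveaxis(idx, -1, 0)
    out = ndimage.map_coordinates(
        image.values, coords.reshape(3, -1), order=1, mode="constant",
        cval=fill_value,
    )
    return out.reshape(pts.shape[:-1])


def warp_pullback(
    moving: ScalarImage, dvf: DisplacementField, fill_value: float | None = None
) -> ScalarImage:
    """Resample ``moving`` through a pull-back field onto the fixed grid.

    ``output(x) = moving(x + u(x))`` for every voxel centre x of
    ``dvf.grid``.
    """
    centers = dvf.grid.voxel_centers()
    sampled = trilinear_sample(moving, centers + dvf.vectors, fill_value)
    return ScalarImage(dvf.grid, sampled)


def resample_to_grid(
    image: ScalarImage, grid: ImageGrid, fill_value: float | None = None
) -> ScalarImage:
    """Trilinearly resample ``image`` onto ``grid``."""
    sampled = trilinear_sample(image, grid.voxel_centers(), fill_value)
    return ScalarImage(grid, sampled)


def resample_field_to_grid(dvf: DisplacementField, grid: ImageGrid) -> DisplacementField:
    """Resample a field onto another grid, preserving mm vector magnitudes.

    Vectors are interpolated componentwise; edge voxels extrapolate by
    nearest-neighbour so constant fields survive grid changes exactly.
    """
    idx = grid.world_to_index(grid.voxel_centers())  # identity, but explicit
    src_idx = dvf.grid.world_to_index(grid.voxel_centers())
    coords = np.moveaxis(src_idx, -1, 0).reshape(3, -1)
    comps = [
        ndimage.map_coordinates(dvf.vectors[..., a], coords, order=1, mode="nearest")
        for a in range(3)
    ]
    vectors = np.stack(comps, axis=-1).reshape(grid.dims + (3,))
    return DisplacementField(grid, vectors)


def _scaled_grid(grid: ImageGrid, factor: float, min_dim: int = 1) -> ImageGrid:
    dims = tuple(max(min_dim, int(np.ceil(d / factor))) for d in grid.dims)
    spacing = tuple(s * d0 / d for s, d0, d in zip(grid.spacing, grid.dims, dims))
    return ImageGrid(dims, spacing, grid.origin)


def downsample_field(dvf: DisplacementField, factor: int) -> DisplacementField:
    """Downsample a field by an integer factor (vectors stay in mm)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return dvf.copy()
    return resample_field_to_grid(dvf, _scaled_grid(dvf.grid, factor))


def upsample_field(dvf: DisplacementField, factor: int) -> DisplacementField:
    """Upsample a field by an integer factor (vectors stay in mm)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return dvf.copy()
    grid = dvf.grid
    dims = tuple(d * factor for d in grid.dims)
    spacing = tuple(s / factor for s in grid.spacing)
    return resample_field_to_grid(dvf, ImageGrid(dims, spacing, grid.origin))
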