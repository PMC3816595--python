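"""ROI propagation between image frames.

Masks travel by displacement-field pull-back (sample the pre-treatment mask
at ``x + u(x)`` and threshold at 0.5); meshes travel by applying a
moving->fixed thin-plate spline to every vertex.  No smoothing is applied
to propagated ROIs.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np
from scipy import ndimage
from skimage import measure

from .image_model import ContourMesh, DisplacementField, ImageGrid, ROIMask
from .sfbr import TPSTransform, evaluate_tps

__all__ = [
    "propagate_mask",
    "propagate_mesh",
    "mask_to_mesh",
    "mesh_to_mask",
]


def propagate_mask(mask_pre: ROIMask, dvf: DisplacementField) -> ROIMask:
    """Pull a pre-treatment mask onto the fixed grid through ``dvf``.

    Each fixed voxel centre ``x`` samples the binary mask trilinearly at
    ``x + u(x)``; the propagated label is 1 iff the sampled value is
    >= 0.5.  No morphological smoothing is applied.
    """
    from .image_model import snap_near_integer_coords

    centers = dvf.grid.voxel_centers() + dvf.vectors
    idx = snap_near_integer_coords(mask_pre.grid.world_to_index(centers))
    coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
    sampled = ndimage.map_coordinates(
        mask_pre.labels.astype(float), coords, order=1, mode="constant", cval=0.0
    ).reshape(dvf.grid.dims)
    return ROIMask(dvf.grid, sampled >= 0.5, mask_pre.name)


def propagate_mesh(mesh_pre: ContourMesh, tps: TPSTransform) -> ContourMesh:
    """Apply a moving->fixed TPS to every mesh vertex; faces unchanged.

    The mesh lives in the pre-treatment (moving) frame, so the transform
    must have been fitted in the propagation direction; a
    ``fixed_to_moving`` transform is rejected.  No post-smoothing.
    """
    if tps.direction != "moving_to_fixed":
        raise ValueError(
            "mesh propagation requires a moving_to_fixed TPS "
            f"(got direction={tps.direction!r})"
        )
    vertices = evaluate_tps(tps, mesh_pre.vertices)
    return ContourMesh(vertices, mesh_pre.faces.copy(), mesh_pre.name)


def mask_to_mesh(mask: ROIMask) -> ContourMesh:
    """Marching-cubes isosurface of a binary mask at level 0.5 (world mm).

    The mask is zero-padded by one voxel so the surface always closes.
    """
    if mask.n_voxels == 0:
        raise ValueError(f"cannot mesh empty mask '{mask.name}'")
    padded = np.pad(mask.labels.astype(float), 1)
    spacing = mask.grid.spacing
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    # undo the one-voxel pad and move to world coordinates
    verts = verts - np.asarray(spacing) + np.asarray(mask.grid.origin)
    return ContourMesh(verts, faces, mask.name)


def mesh_to_mask(mesh: ContourMesh, grid: ImageGrid) -> ROIMask:
    """Voxelize a closed mesh: label voxels whose centres lie inside.

    Inside/outside is decided by ray parity along the slice axis: for each
    in-plane grid column the crossing heights of all triangles are
    collected and voxel centres between odd/even crossing pairs are
    labelled.  Ray origins are jittered off voxel centres by a tiny
    epsilon so rays avoid triangle edges.
    """
    if not mesh.is_closed():
        raise ValueError(f"mesh '{mesh.name}' is not closed; cannot voxelize")
    sp = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    # vertices in continuous index coordinates
    v = (mesh.vertices - origin) / sp
    tri = v[mesh.faces]  # (m, 3, 3)
    eps = 1e-6  # index-space jitter keeps rays off edges/vertices
    crossings: dict[tuple[int, int], list[float]] = defaultdict(list)
    nx, ny, nz = grid.dims
    for a, b, c in tri:
        xy = np.array([a[:2], b[:2], c[:2]])
        lo = np.ceil(xy.min(axis=0) - eps).astype(int)
        hi = np.floor(xy.max(axis=0) + eps).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, (nx - 1, ny - 1))
        if np.any(hi < lo):
            continue
        d1 = xy[1] - xy[0]
        d2 = xy[2] - xy[0]
        det = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(det) < 1e-12:
            continue  # triangle vertical in z: no in-plane area
        for i in range(lo[0], hi[0] + 1):
            px = i + eps - xy[0][0]
            for j in range(lo[1], hi[1] + 1):
                py = j + eps * 0.7 - xy[0][1]
                s = (px * d2[1] - py * d2[0]) / det
                t = (py * d1[0] - px * d1[1]) / det
                if s < 0 or t < 0 or s + t > 1:
                    continue
                z = a[2] + s * (b[2] - a[2]) + t * (c[2] - a[2])
                crossings[(i, j)].append(z)
    labels = np.zeros(grid.dims, dtype=bool)
    n_odd = 0
    for (i, j), zs in crossings.items():
        zs = sorted(zs)
        if len(zs) % 2 == 1:
            n_odd += 1
            zs = zs[:-1]
        for z0, z1 in zip(zs[0::2], zs[1::2]):
            k0 = int(np.ceil(z0))
            k1 = int(np.floor(z1))
            if k1 < k0:
                continue
            labels[i, j, max(k0, 0) : min(k1, nz - 1) + 1] = True
    if n_odd:
        warnings.warn(
            f"{n_odd} columns had an odd crossing count (numerical edge hits); "
            "last crossing dropped",
            stacklevel=2,
        )
    return ROIMask(grid, labels, mesh.name)
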