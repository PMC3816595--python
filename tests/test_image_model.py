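import numpy as np
import pytest

from dirprop.image_model import (
    ContourMesh,
    DisplacementField,
    ImageGrid,
    RigidTransform,
    ROIMask,
    ScalarImage,
    downsample_field,
    resample_to_grid,
    trilinear_sample,
    upsample_field,
    warp_pullback,
)


def oracle_trilinear(image: ScalarImage, point, fill):
    """Independent nested-loop trilinear interpolator.

    Points beyond the voxel-centre hull return the fill value outright.
    """
    idx = (np.asarray(point) - np.asarray(image.grid.origin)) / np.asarray(
        image.grid.spacing
    )
    if any(idx[a] < 0 or idx[a] > image.grid.dims[a] - 1 for a in range(3)):
        return fill
    base = np.floor(idx).astype(int)
    frac = idx - base
    total = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corner = base + (di, dj, dk)
                w = 1.0
                for a, d in enumerate((di, dj, dk)):
                    w *= frac[a] if d else (1.0 - frac[a])
                inside = all(0 <= corner[a] < image.grid.dims[a] for a in range(3))
                v = image.values[tuple(corner)] if inside else fill
                total += w * v
    return total


class TestImageGrid:
    def test_world_index_round_trip(self, ct_grid, rng):
        pts = rng.uniform(0, 30, (20, 3))
        assert np.allclose(ct_grid.index_to_world(ct_grid.world_to_index(pts)), pts)

    def test_voxel_world_coordinate(self):
        grid = ImageGrid((4, 4, 4), (2.0, 2.0, 3.0), (10.0, -5.0, 0.0))
        assert np.allclose(grid.index_to_world((1, 2, 3)), (12.0, -1.0, 9.0))

    @pytest.mark.parametrize(
        "dims,spacing",
        [((0, 4, 4), (1, 1, 1)), ((4, 4, 4), (0.0, 1, 1)), ((4, 4, 4), (1, -1, 1))],
    )
    def test_invalid_grids_rejected(self, dims, spacing):
        with pytest.raises(ValueError):
            ImageGrid(dims, spacing)


class TestTrilinearSample:
    def test_voxel_centre_identity(self, unit_grid, rng):
        img = ScalarImage(unit_grid, rng.normal(size=unit_grid.dims))
        centers = unit_grid.voxel_centers()
        assert np.allclose(trilinear_sample(img, centers), img.values)

    def test_midpoint_linearity(self):
        grid = ImageGrid((2, 1, 1), (1.0, 1.0, 1.0))
        img = ScalarImage(grid, np.array([[[0.0]], [[100.0]]]))
        assert trilinear_sample(img, (0.5, 0.0, 0.0)) == pytest.approx(50.0)

    def test_matches_bruteforce_oracle(self, rng):
        grid = ImageGrid((5, 5, 5), (1.3, 0.9, 2.1), (1.0, -2.0, 0.5))
        img = ScalarImage(grid, rng.normal(size=(5, 5, 5)))
        fill = float(img.values.min())
        pts = rng.uniform(-2.0, 12.0, (10, 3))
        ours = trilinear_sample(img, pts)
        expected = [oracle_trilinear(img, p, fill) for p in pts]
        assert np.allclose(ours, expected, atol=1e-9)

    def test_outside_returns_min_by_default(self, unit_grid, rng):
        img = ScalarImage(unit_grid, rng.uniform(10, 20, unit_grid.dims))
        far = np.array([[100.0, 100.0, 100.0]])
        assert trilinear_sample(img, far)[0] == pytest.approx(img.values.min())

    def test_nonfinite_point_rejected(self, unit_grid, rng):
        img = ScalarImage(unit_grid, rng.normal(size=unit_grid.dims))
        with pytest.raises(ValueError):
            trilinear_sample(img, (np.nan, 0.0, 0.0))


class TestWarpPullback:
    def test_zero_field_identity(self, unit_grid, rng):
        img = ScalarImage(unit_grid, rng.normal(size=unit_grid.dims))
        out = warp_pullback(img, DisplacementField.zeros(unit_grid))
        assert np.array_equal(out.values, img.values)

    def test_constant_field_translates(self, rng):
        grid = ImageGrid((10, 6, 6), (2.0, 1.0, 1.0))
        img = ScalarImage(grid, rng.normal(size=grid.dims))
        vectors = np.zeros(grid.dims + (3,))
        vectors[..., 0] = grid.spacing[0]  # one voxel along x
        out = warp_pullback(img, DisplacementField(grid, vectors))
        assert np.allclose(out.values[:-1], img.values[1:])

    def test_matches_pervoxel_oracle(self, rng):
        grid = ImageGrid((8, 8, 8), (1.0, 1.5, 2.0))
        img = ScalarImage(grid, rng.normal(size=grid.dims))
        centers = grid.voxel_centers()
        smooth = 0.8 * np.sin(centers / 7.0)
        dvf = DisplacementField(grid, smooth)
        out = warp_pullback(img, dvf)
        fill = float(img.values.min())
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    p = centers[i, j, k] + smooth[i, j, k]
                    assert out.values[i, j, k] == pytest.approx(
                        oracle_trilinear(img, p, fill), abs=1e-9
                    )

    def test_inverse_field_round_trip(self, rng):
        # smooth image warped by u then -u comes back within a gradient bound
        grid = ImageGrid((24, 24, 24), (1.0, 1.0, 1.0))
        c = grid.voxel_centers()
        img = ScalarImage(grid, np.sin(c[..., 0] / 4.0) * np.cos(c[..., 1] / 5.0))
        u = np.zeros(grid.dims + (3,))
        u[..., 0] = 0.6 * np.exp(-((c[..., 0] - 12) ** 2 + (c[..., 1] - 12) ** 2) / 50.0)
        warped = warp_pullback(img, DisplacementField(grid, u))
        back = warp_pullback(warped, DisplacementField(grid, -u))
        interior = np.s_[4:-4, 4:-4, 4:-4]
        grad_bound = np.abs(np.gradient(img.values, 1.0)[0]).max() * np.abs(u).max()
        rms = np.sqrt(np.mean((back.values[interior] - img.values[interior]) ** 2))
        assert rms < grad_bound


class TestResampling:
    def test_identity_resample_bitwise(self, unit_grid, rng):
        img = ScalarImage(unit_grid, rng.normal(size=unit_grid.dims))
        out = resample_to_grid(img, unit_grid)
        assert np.array_equal(out.values, img.values)

    def test_upsample_constant_field_preserves_mm(self, unit_grid):
        vectors = np.zeros(unit_grid.dims + (3,))
        vectors[:] = (1.5, -2.0, 0.5)
        up = upsample_field(DisplacementField(unit_grid, vectors), 2)
        assert up.grid.dims == (16, 16, 16)
        assert np.allclose(up.vectors, (1.5, -2.0, 0.5))

    def test_down_up_round_trip_smooth_field(self):
        grid = ImageGrid((32, 32, 32), (1.0, 1.0, 1.0))
        c = grid.voxel_centers()
        vec = np.stack(
            [
                3.0 * np.sin(c[..., 0] / 10.0),
                2.0 * np.cos(c[..., 1] / 12.0),
                np.sin(c[..., 2] / 16.0),
            ],
            axis=-1,
        )
        dvf = DisplacementField(grid, vec)
        from dirprop.image_model import resample_field_to_grid

        down = downsample_field(dvf, 2)
        back = resample_field_to_grid(down, grid)
        rms_err = np.sqrt(np.mean((back.vectors - vec) ** 2))
        rms = np.sqrt(np.mean(vec**2))
        assert rms_err < 0.05 * rms

    def test_downsample_factor_validation(self, unit_grid):
        dvf = DisplacementField.zeros(unit_grid)
        with pytest.raises(ValueError):
            downsample_field(dvf, 0)


class TestRigidTransform:
    def test_identity(self):
        t = RigidTransform.identity()
        pts = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(t.apply(pts), pts)

    def test_rejects_non_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(2 * np.eye(3), np.zeros(3))
        with pytest.raises(ValueError):
            RigidTransform(-np.eye(3), np.zeros(3))

    def test_inverse_compose(self, rng):
        t = RigidTransform.from_params((4.0, -3.0, 3.0), (3.0, -2.0, 5.0), (10, 10, 10))
        pts = rng.normal(size=(5, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-10)
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(ident.translation, 0.0, atol=1e-9)

    def test_rotation_about_center_fixes_center(self):
        center = (5.0, 6.0, 7.0)
        t = RigidTransform.from_params((0, 0, 0), (0, 0, 30.0), center)
        assert np.allclose(t.apply(np.array(center)), center)


class TestMaskAndMesh:
    def test_mask_validation(self, unit_grid):
        with pytest.raises(ValueError):
            ROIMask(unit_grid, np.full(unit_grid.dims, 2))

    def test_mask_volume_and_centroid(self):
        grid = ImageGrid((10, 10, 10), (2.0, 2.0, 3.0))
        labels = np.zeros(grid.dims, dtype=bool)
        labels[2:4, 3:5, 4:6] = True
        mask = ROIMask(grid, labels)
        assert mask.volume_mm3() == pytest.approx(8 * 12.0)
        assert np.allclose(mask.centroid_mm(), grid.index_to_world((2.5, 3.5, 4.5)))

    def test_tetrahedron_closed_and_volume(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        mesh = ContourMesh(verts, faces)
        assert mesh.is_closed()
        assert mesh.volume_mm3() == pytest.approx(1.0 / 6.0)

    def test_open_mesh_detected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        mesh = ContourMesh(verts, np.array([[0, 1, 2]]))
        assert not mesh.is_closed()

    def test_face_index_validation(self):
        with pytest.raises(ValueError):
            ContourMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))
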