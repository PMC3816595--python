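import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dirprop.image_model import ImageGrid, ROIMask
from dirprop.metrics import (
    com_distance,
    dice,
    mshd,
    mshd_detail,
    one_way_anova,
    point_biserial,
    score_to_binary_group,
    volume_change_table,
)

from conftest import random_blob_mask


# --- independent oracles -----------------------------------------------------


def oracle_dice(a: ROIMask, b: ROIMask) -> float:
    sa = {tuple(i) for i in np.argwhere(a.labels)}
    sb = {tuple(i) for i in np.argwhere(b.labels)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def oracle_boundary(labels2d):
    pts = []
    nx, ny = labels2d.shape
    for i in range(nx):
        for j in range(ny):
            if not labels2d[i, j]:
                continue
            neighbours = []
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                neighbours.append(
                    labels2d[ii, jj] if 0 <= ii < nx and 0 <= jj < ny else False
                )
            if not all(neighbours):
                pts.append((i, j))
    return pts


def oracle_mshd(a: ROIMask, b: ROIMask):
    """Exhaustive per-slice all-pairs symmetric Hausdorff mean."""
    sx, sy = a.grid.spacing[:2]
    per_slice = []
    for k in range(a.grid.dims[2]):
        sa, sb = a.labels[:, :, k], b.labels[:, :, k]
        if not sa.any() or not sb.any():
            continue
        pa = [(i * sx, j * sy) for i, j in oracle_boundary(sa)]
        pb = [(i * sx, j * sy) for i, j in oracle_boundary(sb)]
        d_ab = max(min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in pb) for p in pa)
        d_ba = max(min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in pa) for p in pb)
        per_slice.append(max(d_ab, d_ba))
    return float(np.mean(per_slice)) if per_slice else None


# --- Dice --------------------------------------------------------------------


class TestDice:
    def test_identical_masks(self, ct_grid, rng):
        m = random_blob_mask(ct_grid, rng)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        grid = ImageGrid((10, 10, 4), (1, 1, 1))
        la = np.zeros(grid.dims, dtype=bool)
        lb = np.zeros(grid.dims, dtype=bool)
        la[:3], lb[6:] = True, True
        assert dice(ROIMask(grid, la), ROIMask(grid, lb)) == 0.0

    def test_hand_counted_half_overlap(self):
        # 2x2x2 cube shifted by one voxel: overlap 4 of 8 -> 2*4/16 = 0.5
        grid = ImageGrid((6, 6, 6), (1, 1, 1))
        la = np.zeros(grid.dims, dtype=bool)
        lb = np.zeros(grid.dims, dtype=bool)
        la[1:3, 1:3, 1:3] = True
        lb[2:4, 1:3, 1:3] = True
        assert dice(ROIMask(grid, la), ROIMask(grid, lb)) == pytest.approx(0.5)

    def test_both_empty_warns_one(self, ct_grid):
        a = ROIMask(ct_grid, np.zeros(ct_grid.dims, dtype=bool))
        with pytest.warns(UserWarning):
            assert dice(a, a) == 1.0

    def test_grid_mismatch_rejected(self, ct_grid, unit_grid):
        a = ROIMask(ct_grid, np.ones(ct_grid.dims, dtype=bool))
        b = ROIMask(unit_grid, np.ones(unit_grid.dims, dtype=bool))
        with pytest.raises(ValueError):
            dice(a, b)

    def test_symmetry_and_oracle(self, rng):
        grid = ImageGrid((12, 12, 3), (1.1, 0.8, 2.5))
        for _ in range(20):
            a = random_blob_mask(grid, rng, "a")
            b = random_blob_mask(grid, rng, "b")
            assert dice(a, b) == dice(b, a)
            assert dice(a, b) == pytest.approx(oracle_dice(a, b), abs=1e-12)


# --- MSHD --------------------------------------------------------------------


class TestMSHD:
    def test_identical_masks_zero(self, rng):
        grid = ImageGrid((16, 16, 4), (1, 1, 3))
        m = random_blob_mask(grid, rng)
        assert mshd(m, m) == 0.0

    def test_two_point_hausdorff(self):
        grid = ImageGrid((12, 12, 1), (1.0, 1.0, 3.0))
        la = np.zeros(grid.dims, dtype=bool)
        lb = np.zeros(grid.dims, dtype=bool)
        la[2, 5, 0] = True
        lb[7, 5, 0] = True  # 5 voxels = 5 mm apart in-plane
        assert mshd(ROIMask(grid, la), ROIMask(grid, lb)) == pytest.approx(5.0)

    def test_symmetry(self, rng):
        grid = ImageGrid((20, 20, 4), (0.98, 0.98, 3.0))
        a = random_blob_mask(grid, rng, "a")
        b = random_blob_mask(grid, rng, "b")
        assert mshd(a, b) == mshd(b, a)

    def test_matches_exhaustive_oracle(self, rng):
        grid = ImageGrid((16, 16, 4), (1.2, 0.7, 3.0))
        checked = 0
        while checked < 10:
            a = random_blob_mask(grid, rng, "a")
            b = random_blob_mask(grid, rng, "b")
            expected = oracle_mshd(a, b)
            if expected is None:
                continue
            assert mshd(a, b) == pytest.approx(expected, abs=1e-9)
            checked += 1

    def test_one_sided_slices_excluded_and_counted(self):
        grid = ImageGrid((8, 8, 3), (1, 1, 1))
        la = np.zeros(grid.dims, dtype=bool)
        lb = np.zeros(grid.dims, dtype=bool)
        la[3:5, 3:5, 0] = True
        lb[3:5, 3:5, 0] = True
        la[3:5, 3:5, 1] = True  # present only in a
        detail = mshd_detail(ROIMask(grid, la), ROIMask(grid, lb))
        assert detail.mshd_mm == 0.0
        assert detail.n_slices_compared == 1
        assert detail.n_slices_one_sided == 1
        # with a penalty the one-sided slice enters the mean
        with_penalty = mshd_detail(
            ROIMask(grid, la), ROIMask(grid, lb), one_sided_penalty_mm=10.0
        )
        assert with_penalty.mshd_mm == pytest.approx(5.0)

    def test_never_cooccurring_masks_rejected(self):
        grid = ImageGrid((8, 8, 2), (1, 1, 1))
        la = np.zeros(grid.dims, dtype=bool)
        lb = np.zeros(grid.dims, dtype=bool)
        la[3, 3, 0] = True
        lb[3, 3, 1] = True
        with pytest.raises(ValueError, match="no comparable slices"):
            mshd(ROIMask(grid, la), ROIMask(grid, lb))


# --- COM ---------------------------------------------------------------------


class TestCOMDistance:
    def test_identical(self, ct_grid, rng):
        m = random_blob_mask(ct_grid, rng)
        assert com_distance(m, m) == 0.0

    def test_single_voxels_13mm(self):
        grid = ImageGrid((20, 4, 4), (1.0, 1.0, 1.0))
        la = np.zeros(grid.dims, dtype=bool)
        lb = np.zeros(grid.dims, dtype=bool)
        la[2, 1, 1] = True
        lb[15, 1, 1] = True  # 13 mm apart
        assert com_distance(ROIMask(grid, la), ROIMask(grid, lb)) == pytest.approx(1.3)

    def test_matches_explicit_centroids(self, rng):
        grid = ImageGrid((16, 16, 8), (1.7, 0.9, 2.2), (3.0, -1.0, 7.0))
        a = random_blob_mask(grid, rng, "a")
        b = random_blob_mask(grid, rng, "b")
        ca = np.array(
            [grid.index_to_world(i) for i in np.argwhere(a.labels)]
        ).mean(axis=0)
        cb = np.array(
            [grid.index_to_world(i) for i in np.argwhere(b.labels)]
        ).mean(axis=0)
        assert com_distance(a, b) == pytest.approx(
            np.linalg.norm(ca - cb) / 10.0, abs=1e-12
        )

    def test_empty_mask_rejected(self, ct_grid, rng):
        a = random_blob_mask(ct_grid, rng)
        empty = ROIMask(ct_grid, np.zeros(ct_grid.dims, dtype=bool))
        with pytest.raises(ValueError):
            com_distance(a, empty)


# --- volume change -----------------------------------------------------------


class TestVolumeChangeTable:
    def test_printed_rows(self):
        assert volume_change_table([15.8], [14.5])["table"].percent_difference[
            0
        ] == pytest.approx(8.2)
        assert volume_change_table([96.6], [111.4])["table"].percent_difference[
            0
        ] == pytest.approx(-15.3)
        assert volume_change_table([59.6], [65.7])["table"].percent_difference[
            0
        ] == pytest.approx(-10.2)

    def test_no_change_zero_percent(self):
        out = volume_change_table([10.0, 20.0], [10.0, 20.0])
        assert np.all(out["table"].percent_difference == 0.0)
        assert out["n_decreased"] == 0 and out["n_increased"] == 0

    def test_counts(self):
        out = volume_change_table([10, 10, 10], [8, 12, 10.5])
        assert out["n_decreased"] == 1
        assert out["n_increased"] == 2
        assert out["n_increased_over_10pct"] == 1  # only the +20% case

    def test_zero_pre_volume_rejected(self):
        with pytest.raises(ValueError):
            volume_change_table([0.0], [1.0])


# --- ANOVA -------------------------------------------------------------------


class TestOneWayAnova:
    def test_identical_groups(self):
        f, p, sig = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == 0.0 and p == 1.0 and not sig

    def test_textbook_hand_computation(self):
        # groups {1,2,3},{4,5,6}: SSB = 13.5, SSW = 4, df = (1, 4) -> F = 13.5
        f, p, sig = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5)
        assert sig

    def test_matches_scipy(self, rng):
        groups = [rng.normal(loc, 1.0, size=12) for loc in (0.0, 0.3, 1.0)]
        f, p, _ = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])


# --- point-biserial ----------------------------------------------------------


class TestPointBiserial:
    def test_identical_values_r_zero(self):
        r, p = point_biserial([0, 0, 1, 1], [5.0, 5.0, 5.0, 5.0])
        assert r == 0.0 and p == 1.0

    def test_perfect_separation(self):
        r, p = point_biserial([0, 0, 1, 1], [0.0, 0.0, 1.0, 1.0])
        assert abs(r) == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_pearson_identity(self, rng):
        g = rng.integers(0, 2, 40)
        g[0], g[1] = 0, 1  # both classes present
        v = rng.normal(size=40)
        r, p = point_biserial(g, v)
        pearson = np.corrcoef(g, v)[0, 1]
        assert r == pytest.approx(pearson, abs=1e-12)
        ref = stats.pearsonr(g, v)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            point_biserial([1, 1, 1], [1.0, 2.0, 3.0])

    def test_score_grouping(self):
        assert np.array_equal(
            score_to_binary_group([1, 2, 3, 1, 2]), [0, 1, 1, 0, 1]
        )
        with pytest.raises(ValueError):
            score_to_binary_group([0, 1])


# --- property tests ----------------------------------------------------------


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 1), min_size=8, max_size=8), st.data())
def test_point_biserial_bounded_and_symmetric_under_negation(groups, data):
    if 0 not in groups or 1 not in groups:
        return
    values = data.draw(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=8, max_size=8
        )
    )
    r, _ = point_biserial(groups, values)
    assert -1.0 <= r <= 1.0
    r_neg, _ = point_biserial(groups, [-v for v in values])
    assert r_neg == pytest.approx(-r, abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0.5, 500.0, allow_nan=False), min_size=1, max_size=20),
    st.data(),
)
def test_volume_change_counts_partition(pre, data):
    mid = data.draw(
        st.lists(
            st.floats(0.5, 500.0, allow_nan=False),
            min_size=len(pre),
            max_size=len(pre),
        )
    )
    out = volume_change_table(pre, mid)
    unchanged = sum(1 for p, m in zip(pre, mid) if p == m)
    assert out["n_decreased"] + out["n_increased"] + unchanged == len(pre)
    assert out["n_increased_over_10pct"] <= out["n_increased"]
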