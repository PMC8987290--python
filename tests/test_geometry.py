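"""Separation metrics against analytic cases and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import exhaustive_signflip_p, ovh_distances_pairwise, rnnd_bruteforce
from spacersim import geometry
from spacersim.grid import VoxelGrid


GRID1 = VoxelGrid((30, 30, 30), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def cube(grid, lo, hi):
    m = np.zeros(grid.shape, bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


class TestDSC:
    def test_identical_masks(self):
        a = cube(GRID1, (5, 5, 5), (15, 15, 15))
        assert geometry.dsc(a, a) == 1.0

    def test_disjoint_masks(self):
        a = cube(GRID1, (0, 0, 0), (5, 5, 5))
        b = cube(GRID1, (10, 10, 10), (20, 20, 20))
        assert geometry.dsc(a, b) == 0.0

    def test_half_overlapping_cubes(self):
        # two 10^3 cubes sharing a 10 x 10 x 5 slab: 2*500 / 2000 = 0.5
        a = cube(GRID1, (0, 0, 0), (10, 10, 10))
        b = cube(GRID1, (0, 0, 5), (10, 10, 15))
        assert geometry.dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_is_nan(self):
        z = np.zeros(GRID1.shape, bool)
        assert np.isnan(geometry.dsc(z, z))

    @given(st.integers(0, 2**30))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8, 8)) > 0.6
        b = rng.random((8, 8, 8)) > 0.6
        if not (a.any() or b.any()):
            return
        d = geometry.dsc(a, b)
        assert 0.0 <= d <= 1.0
        assert d == geometry.dsc(b, a)


class TestMargin:
    def test_solid_cube_has_26_margin_voxels(self):
        m = cube(GRID1, (10, 10, 10), (13, 13, 13))
        assert geometry.extract_margin(m, GRID1).shape[0] == 26

    def test_single_voxel(self):
        m = np.zeros(GRID1.shape, bool)
        m[4, 5, 6] = True
        pts = geometry.extract_margin(m, GRID1)
        assert pts.shape == (1, 3)
        np.testing.assert_allclose(pts[0], [4.0, 5.0, 6.0])

    def test_hollow_shell_has_inner_and_outer_surface(self):
        xx, yy, zz = np.meshgrid(*[np.arange(30) - 14.5] * 3, indexing="ij")
        r2 = xx**2 + yy**2 + zz**2
        shell = (r2 <= 100) & (r2 >= 36)
        pts = geometry.extract_margin(shell, GRID1)
        radii = np.linalg.norm(pts - 14.5, axis=1)
        assert (radii < 8).any() and (radii > 8.5).any()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            geometry.extract_margin(np.zeros(GRID1.shape, bool), GRID1)


class TestOVH:
    def test_distant_oar_lower_bounds_l1cc(self):
        grid = VoxelGrid((40, 60, 40), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        target = cube(grid, (5, 5, 5), (15, 15, 15))
        oar = cube(grid, (5, 22, 5), (20, 52, 20))  # >= 7 mm away, 6.75 cc... scaled below
        curve = geometry.ovh(target, oar, grid)
        assert curve.oar_volume_cc >= 6.0
        assert curve.threshold(1) >= 7.0

    def test_full_overlap_gives_negative_thresholds(self):
        grid = VoxelGrid((40, 40, 40), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        mask = cube(grid, (3, 3, 3), (34, 34, 34))  # ~29.8 cc
        curve = geometry.ovh(mask, mask, grid)
        assert curve.threshold(1) < 0
        assert curve.threshold(20) <= 0

    def test_undefined_threshold_for_small_oar(self):
        target = cube(GRID1, (5, 5, 5), (10, 10, 10))
        oar = cube(GRID1, (15, 15, 15), (20, 20, 20))  # 0.125 cc
        curve = geometry.ovh(target, oar, GRID1)
        assert curve.threshold(1) is None

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pairwise_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = VoxelGrid((24, 24, 24), (1.5, 1.5, 1.5), (0.0, 0.0, 0.0))
        target = np.zeros(grid.shape, bool)
        target[4:10, 4:10, 4:10] = True
        oar = rng.random(grid.shape) > 0.7
        oar[:, :6, :] = False
        curve = geometry.ovh(target, oar, grid, volumes_cc=(0.1, 0.3))
        d_oracle = np.sort(ovh_distances_pairwise(target, oar, grid))
        voxvol = grid.voxel_volume_cc
        for v in (0.1, 0.3):
            k = int(np.ceil(v / voxvol))
            expected = d_oracle[k - 1]
            # within the half-voxel sampling step of the curve
            assert abs(curve.threshold(v) - expected) <= min(grid.spacing) / 2 + 1e-9


class TestRNND:
    def test_concentric_circles_give_constant_gap(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        inner = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)])
        outer = np.column_stack([15 * np.cos(t), 15 * np.sin(t), np.zeros_like(t)])
        prof = geometry.rnnd(inner, outer, origin=np.zeros(3), bin_width_deg=5.0)
        assert not prof.empty.any()
        np.testing.assert_allclose(prof.mean_mm, 5.0, atol=0.05)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_exactly(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 20, size=(400, 3))
        b = rng.normal(0, 20, size=(350, 3))
        origin = np.array([1.0, -2.0, 0.5])
        prof = geometry.rnnd(a, b, origin=origin, bin_width_deg=15.0, reference_deg=30.0)
        mean_o, p5_o = rnnd_bruteforce(a, b, origin, 15.0, reference_deg=30.0)
        np.testing.assert_allclose(prof.mean_mm, mean_o, equal_nan=True, atol=1e-12)
        np.testing.assert_allclose(prof.p5_mm, p5_o, equal_nan=True, atol=1e-12)

    def test_self_distance_is_zero(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 10, size=(200, 3))
        prof = geometry.rnnd(a, a, origin=np.zeros(3))
        assert np.nanmax(prof.mean_mm) == 0.0

    def test_p5_below_mean_where_defined(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 15, size=(500, 3))
        b = rng.normal(0, 15, size=(500, 3))
        prof = geometry.rnnd(a, b, origin=np.zeros(3), bin_width_deg=30.0)
        ok = ~prof.empty
        assert np.all(prof.p5_mm[ok] <= prof.mean_mm[ok] + 1e-12)


class TestNormalize:
    def test_single_case_max_is_one(self):
        samples = np.array([1.0, 2.0, 4.0])
        pooled = geometry.normalize_profiles([samples], [4.0])
        assert pooled.max() == 1.0

    def test_histogram_has_unit_mass(self):
        rng = np.random.default_rng(0)
        pooled = geometry.normalize_profiles(
            [rng.random(100), rng.random(80)], [1.0, 2.0]
        )
        hist, edges = geometry.pooled_histogram(pooled)
        assert np.sum(hist * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        x = np.array([1.0, 3.0, 5.0])
        a = geometry.normalize_profiles([x], [5.0])
        b = geometry.normalize_profiles([2 * x], [10.0])
        np.testing.assert_allclose(a, b)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            geometry.normalize_profiles([np.ones(3)], [0.0])


class TestPairedPermutation:
    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        assert geometry.paired_permutation_test(x, x) == 1.0

    def test_matches_exhaustive_enumeration_at_n6(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1.0, 1.0, 6)
        y = rng.normal(0.0, 1.0, 6)
        exact = exhaustive_signflip_p(x - y)
        p = geometry.paired_permutation_test(x, y, n_perm=4000, seed=0)
        mc_err = 3 * np.sqrt(exact * (1 - exact) / 4000) + 1 / 4000
        assert abs(p - exact) <= mc_err + 0.01

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(5.0, 1.0, 15)
        y = rng.normal(0.0, 1.0, 15)
        assert geometry.paired_permutation_test(x, y, seed=1) < 0.01
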