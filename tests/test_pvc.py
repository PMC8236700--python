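"""Partial volume correction: neighborhoods, LAD solver, unmixing, resampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linprog

from cvrkit.errors import GeometryError
from cvrkit.grids import Grid, nn_resample
from cvrkit.pvc import (
    NeighborhoodSpec,
    apply_pvc,
    downsample_fractions,
    lad_solve,
    neighborhood_offsets,
    solve_voxel_pvc,
)


def lad_lp_oracle(A, b):
    """Reference least-absolute-deviations solution via linear programming.

    min sum(u + v) s.t. A x + u - v = b, u, v >= 0.
    """
    m, k = A.shape
    c = np.concatenate([np.zeros(k), np.ones(2 * m)])
    A_eq = np.hstack([A, np.eye(m), -np.eye(m)])
    bounds = [(None, None)] * k + [(0, None)] * (2 * m)
    res = linprog(c, A_eq=A_eq, b_eq=b, bounds=bounds, method="highs")
    assert res.success
    return res.x[:k]


def brute_force_offsets(radius, voxel_size):
    size = np.asarray(voxel_size, dtype=float)
    n = 6  # generous bound for radii <= 15 mm on >= 2.3 mm voxels
    out = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                d = np.sqrt(((np.array([i, j, k]) * size) ** 2).sum())
                if d <= radius + 1e-9:
                    out.append((i, j, k))
    return set(out)


class TestNeighborhoodOffsets:
    @pytest.mark.parametrize("radius,expected", [(9.0, 81), (5.0, 19),
                                                 (7.0, 33), (11.0, 123)])
    def test_isotropic_counts(self, radius, expected):
        spec = NeighborhoodSpec(radius, (3.5, 3.5, 3.5))
        offsets = neighborhood_offsets(spec)
        assert len(offsets) == expected

    def test_zero_radius_is_self_only(self):
        offsets = neighborhood_offsets(NeighborhoodSpec(0.0, (3.5, 3.5, 3.5)))
        assert offsets.shape == (1, 3)
        assert tuple(offsets[0]) == (0, 0, 0)

    @given(radius=st.floats(0.0, 15.0),
           vz=st.floats(2.5, 6.0))
    def test_matches_brute_force_enumeration(self, radius, vz):
        spec = NeighborhoodSpec(radius, (3.5, 3.5, vz))
        got = {tuple(o) for o in neighborhood_offsets(spec)}
        assert got == brute_force_offsets(radius, (3.5, 3.5, vz))


class TestDownsampleFractions:
    def test_pure_tissue_block(self):
        hi = Grid.from_spacing((7, 7, 7), 1.0)
        lo = Grid.from_spacing((2, 2, 2), 3.5)
        probs = np.zeros((7, 7, 7, 3))
        probs[..., 0] = 1.0
        frac = downsample_fractions(probs, hi, lo)
        np.testing.assert_allclose(frac[..., 0], 1.0)
        np.testing.assert_allclose(frac[..., 1:], 0.0)

    def test_half_and_half_symmetry(self):
        hi = Grid.from_spacing((8, 4, 4), 1.0)
        lo = Grid.from_spacing((2, 1, 1), 4.0)
        probs = np.zeros((8, 4, 4, 3))
        probs[:4, ..., 0] = 1.0      # left half GM
        probs[4:, ..., 1] = 1.0      # right half WM
        frac = downsample_fractions(probs, hi, lo)
        np.testing.assert_allclose(frac[0, 0, 0], [1.0, 0.0, 0.0])
        # a voxel straddling both halves equally
        lo_mid = Grid.from_spacing((1, 1, 1), 4.0, origin=(2.0, 0.0, 0.0))
        frac_mid = downsample_fractions(probs, hi, lo_mid)
        np.testing.assert_allclose(frac_mid[0, 0, 0], [0.5, 0.5, 0.0])

    def test_81_19_footprint(self):
        """A footprint covering 81% GM and 19% WM voxels yields (0.81, 0.19, 0)."""
        hi = Grid.from_spacing((100, 1, 1), 1.0)
        lo = Grid.from_spacing((1, 1, 1), (100.0, 1.0, 1.0))
        probs = np.zeros((100, 1, 1, 3))
        probs[:81, ..., 0] = 1.0
        probs[81:, ..., 1] = 1.0
        frac = downsample_fractions(probs, hi, lo)
        np.testing.assert_allclose(frac[0, 0, 0], [0.81, 0.19, 0.0])

    def test_disjoint_grids_raise(self):
        hi = Grid.from_spacing((4, 4, 4), 1.0)
        lo = Grid.from_spacing((2, 2, 2), 3.5, origin=(1000.0, 0.0, 0.0))
        with pytest.raises(GeometryError):
            downsample_fractions(np.zeros((4, 4, 4, 3)), hi, lo)


def random_consistent_system(rng, n=81, n_outliers=0):
    """Full-rank fractions and intensities exactly mixing a known truth."""
    truth = np.array([0.30, 0.10, 0.05])
    frac = rng.dirichlet([2.0, 2.0, 1.0], size=n)
    b = frac @ truth
    if n_outliers:
        idx = rng.choice(n, size=n_outliers, replace=False)
        b[idx] += rng.normal(10.0, 3.0, size=n_outliers)
    return frac, b, truth


class TestSolveVoxelPvc:
    def test_consistent_system_recovered_exactly(self):
        rng = np.random.default_rng(0)
        frac, b, truth = random_consistent_system(rng)
        sol = solve_voxel_pvc(b, frac, present_classes=[True, True, True])
        assert sol.rank_ok
        np.testing.assert_allclose(sol.as_array(), truth, atol=1e-8)

    def test_outliers_leave_lad_exact_but_bias_least_squares(self):
        rng = np.random.default_rng(1)
        frac, b, truth = random_consistent_system(rng, n_outliers=1)
        sol = solve_voxel_pvc(b, frac, present_classes=[True, True, True])
        np.testing.assert_allclose(sol.as_array(), truth, atol=1e-8)
        ls = np.linalg.lstsq(frac, b, rcond=None)[0]
        assert np.max(np.abs(ls - truth)) > 1e-3

    def test_absent_class_not_assigned(self):
        rng = np.random.default_rng(2)
        frac, b, truth = random_consistent_system(rng)
        sol = solve_voxel_pvc(b, frac, present_classes=[True, True, False])
        assert np.isnan(sol.i_c)
        assert sol.i_g == pytest.approx(truth[0], abs=1e-8)

    def test_single_class_neighborhood(self):
        frac = np.zeros((10, 3))
        frac[:, 0] = 1.0
        sol = solve_voxel_pvc(np.full(10, 0.3), frac, [True, False, False])
        assert sol.rank_ok
        assert sol.i_g == pytest.approx(0.3)
        assert np.isnan(sol.i_w) and np.isnan(sol.i_c)

    def test_too_few_neighbors_withheld(self):
        sol = solve_voxel_pvc(np.array([0.3, 0.2]), np.full((2, 3), 1 / 3),
                              [True, True, True])
        assert not sol.rank_ok
        assert np.isnan(sol.as_array()).all()

    def test_rank_deficient_design_withheld(self):
        frac = np.tile([0.5, 0.5, 0.0], (20, 1))   # GM and WM columns collinear
        sol = solve_voxel_pvc(np.full(20, 0.2), frac, [True, True, False])
        assert not sol.rank_ok

    @pytest.mark.parametrize("n_outliers", [0, 4, 8])
    def test_lad_matches_linear_programming_oracle(self, n_outliers):
        rng = np.random.default_rng(100 + n_outliers)
        for _ in range(10):
            frac, b, _ = random_consistent_system(rng, n_outliers=n_outliers)
            x_irls = lad_solve(frac, b)
            x_lp = lad_lp_oracle(frac, b)
            np.testing.assert_allclose(x_irls, x_lp, atol=1e-6)

    def test_remixing_reproduces_center_intensity(self):
        """Conservation: V0's fractions applied to the solution reproduce I0
        within the neighborhood's LAD residual scale."""
        rng = np.random.default_rng(3)
        frac, b, _ = random_consistent_system(rng)
        noisy = b + rng.normal(0, 0.01, b.size)
        sol = solve_voxel_pvc(noisy, frac, [True, True, True])
        resid_scale = np.mean(np.abs(noisy - frac @ sol.as_array()))
        assert abs(frac[0] @ sol.as_array() - noisy[0]) <= 5 * resid_scale + 1e-9


class TestNnResample:
    def test_integer_ratio_block_replication(self):
        lo = Grid.from_spacing((2, 2, 2), 4.0)
        hi = Grid.from_spacing((8, 8, 8), 1.0)
        vol = np.arange(8.0).reshape(2, 2, 2)
        out = nn_resample(vol, lo, hi)
        assert out.shape == (8, 8, 8)
        for i in range(2):
            np.testing.assert_array_equal(out[4 * i : 4 * i + 4, :4, :4],
                                          vol[i, 0, 0])

    def test_constant_map_stays_constant(self):
        lo = Grid.from_spacing((3, 3, 3), 3.5)
        hi = Grid.from_spacing((10, 10, 10), 1.0)
        out = nn_resample(np.full((3, 3, 3), 7.0), lo, hi)
        assert np.all(out == 7.0)

    def test_boundary_ties_go_to_lower_index(self):
        """Two 3.5 mm voxels [1, 2] onto a 1 mm grid: the high-res voxel
        centered exactly between the two low-res centers takes value 1."""
        lo = Grid.from_spacing((2, 1, 1), (3.5, 1.0, 1.0))
        hi = Grid.from_spacing((7, 1, 1), (1.0, 1.0, 1.0))
        out = nn_resample(np.array([[[1.0]], [[2.0]]]), lo, hi)
        centers = hi.axis_centers(0)          # 0.5, 1.5, ..., 6.5
        lo_centers = lo.axis_centers(0)       # 1.75 and 5.25; midpoint 3.5
        d = np.abs(centers[:, None] - lo_centers[None, :])
        expected = np.where(d[:, 0] <= d[:, 1], 1.0, 2.0)
        np.testing.assert_array_equal(out[:, 0, 0], expected)
        assert centers[3] == 3.5 and out[3, 0, 0] == 1.0   # exact tie -> lower


class TestApplyPvc:
    def make_mixed_volume(self, rng, shape=(8, 8, 6), truth=(0.3, 0.1, 0.05)):
        """Low-res volume whose intensities exactly mix constant class values."""
        frac = rng.dirichlet([3.0, 3.0, 1.0], size=shape).reshape(shape + (3,))
        intensity = frac @ np.asarray(truth)
        return frac, intensity

    def test_exact_unmixing_of_consistent_low_res_volume(self):
        rng = np.random.default_rng(5)
        shape = (8, 8, 6)
        frac, intensity = self.make_mixed_volume(rng, shape)
        lo = Grid.from_spacing(shape, 3.5)
        # high-res grid with one pure class per voxel (majority assignment)
        hi_shape = (28, 28, 21)
        hi = Grid.from_spacing(hi_shape, 1.0)
        probs = np.zeros(hi_shape + (3,))
        cls = rng.integers(0, 3, size=hi_shape)
        for c in range(3):
            probs[..., c] = cls == c
        mask = np.ones(shape, dtype=bool)
        res = apply_pvc(intensity, frac, mask, lo, probs, hi)
        truth = np.array([0.3, 0.1, 0.05])
        for c in range(3):
            sel = cls == c
            np.testing.assert_allclose(res.highres[sel], truth[c], atol=1e-8)

    def test_fallback_when_neighborhood_degenerate(self):
        """A rank-deficient neighborhood keeps the uncorrected value, flagged."""
        shape = (4, 4, 4)
        frac = np.zeros(shape + (3,))
        frac[..., 0] = 0.5
        frac[..., 1] = 0.5            # collinear columns everywhere
        intensity = np.full(shape, 0.2)
        lo = Grid.from_spacing(shape, 3.5)
        hi = Grid.from_spacing((14, 14, 14), 1.0)
        probs = np.zeros((14, 14, 14, 3))
        probs[..., 0] = 1.0
        res = apply_pvc(intensity, frac, np.ones(shape, bool), lo, probs, hi)
        assert res.fallback.all()
        assert res.fallback_fraction == pytest.approx(1.0)
        np.testing.assert_allclose(res.highres, 0.2)

    def test_masked_out_neighbors_are_excluded(self):
        """Corrupt values outside the mask must not influence the solution."""
        rng = np.random.default_rng(6)
        shape = (8, 8, 6)
        frac, intensity = self.make_mixed_volume(rng, shape)
        mask = np.ones(shape, dtype=bool)
        mask[0] = False
        intensity = intensity.copy()
        intensity[0] = 1e6
        lo = Grid.from_spacing(shape, 3.5)
        hi = Grid.from_spacing((28, 28, 21), 1.0)
        probs = np.zeros((28, 28, 21, 3))
        probs[..., 0] = 1.0
        res = apply_pvc(intensity, frac, mask, lo, probs, hi)
        inside = np.isfinite(res.highres)
        np.testing.assert_allclose(res.highres[inside], 0.3, atol=1e-8)
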