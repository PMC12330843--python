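import numpy as np
import pytest

from emct2.b1map import B1Maps
from emct2.match import (MatchConfig, match_curves, match_voxels,
                         normalize_signal, two_pass_fit)
from emct2.noise import NoiseEstimate, SNRMap, ncchi_sample


class TestNormalize:
    def test_three_four_five(self):
        unit, rho = normalize_signal(np.array([3.0, 4.0]))
        assert np.allclose(unit, [0.6, 0.8])
        assert rho == 5.0

    def test_unit_curve_unchanged(self):
        curve = np.array([1.0, 0.0, 0.0])
        unit, rho = normalize_signal(curve)
        assert np.array_equal(unit, curve)
        assert rho == 1.0

    def test_zero_curve_flagged(self):
        unit, rho = normalize_signal(np.zeros(7))
        assert rho == 0.0


class TestMatchCurves:
    def test_identity_recovery_every_row(self, small_dictionary):
        """Feeding back every dictionary row recovers its exact parameters."""
        d = small_dictionary
        res = match_curves(d.curves * 7.3, d, None, 0.0)
        t2, b1 = d.entry_params()
        assert np.array_equal(res["t2_ms"], t2)
        assert np.array_equal(res["b1_fraction"], b1)
        assert np.allclose(res["s0"], 7.3 / d.rho_theta, rtol=1e-9)

    def test_huge_lambda_clamps_b1_to_regularizer(self, small_dictionary):
        d = small_dictionary
        curves = d.curves[:50] * 2.0
        reg = np.full(50, 0.93)
        res = match_curves(curves, d, reg, 1e6)
        # grid is 0.70:1.30:0.05 -> nearest node to 0.93 is 0.95
        assert np.allclose(res["b1_fraction"], 0.95)

    def test_off_grid_t2_matches_nearest_node(self, protocol):
        """A mono-exponential off the grid by < step/2 lands on the nearest node."""
        from emct2.dictionary import SimConfig, build_dictionary, make_grid
        from emct2.sequence import MESEProtocol
        p180 = MESEProtocol(refocusing_flip_deg=180.0)
        grid = make_grid(((20.0, 80.0, 5.0),), (1.0, 1.0, 0.01))
        d = build_dictionary(grid, p180, SimConfig(mode="ideal"))
        tes = p180.echo_times_ms
        for t2 in (41.0, 43.8, 67.4):
            res = match_curves(np.exp(-tes / t2)[None, :], d, None, 0.0)
            nearest = grid.t2_ms[np.argmin(np.abs(grid.t2_ms - t2))]
            assert res["t2_ms"][0] == nearest

    def test_scale_invariance(self, small_dictionary, rng):
        d = small_dictionary
        curves = rng.random((20, d.etl)) + 0.1
        a = match_curves(curves, d, None, 0.0)
        b = match_curves(curves * 123.4, d, None, 0.0)
        assert np.array_equal(a["idx"], b["idx"])
        assert np.allclose(b["s0"], 123.4 * a["s0"])

    def test_batch_size_independence(self, small_dictionary, rng):
        d = small_dictionary
        curves = rng.random((101, d.etl)) + 0.1
        reg = rng.uniform(0.8, 1.2, 101)
        a = match_curves(curves, d, reg, 1.0, batch_size=7)
        b = match_curves(curves, d, reg, 1.0, batch_size=4096)
        assert np.array_equal(a["idx"], b["idx"])

    def test_echo_count_mismatch_rejected(self, small_dictionary):
        with pytest.raises(ValueError):
            match_curves(np.ones((3, 5)), small_dictionary)


class TestMatchVoxels:
    def _stack_from_rows(self, d, rows, shape):
        curves = d.curves[rows] * d.rho_theta[rows, None]
        return curves.reshape(shape + (d.etl,))

    def test_mapset_fields_consistent(self, small_dictionary):
        d = small_dictionary
        rows = np.arange(24)
        stack = self._stack_from_rows(d, rows, (2, 3, 4))
        maps = match_voxels(stack, d, None)
        assert np.allclose(maps.r2, 1000.0 / maps.t2, equal_nan=True)
        assert np.all(maps.residual[np.isfinite(maps.residual)] >= 0)
        assert np.all(maps.total_cost >= maps.residual - 1e-15)
        assert not maps.excluded.any()

    def test_snr_exclusion_writes_nan_and_mask(self, small_dictionary):
        d = small_dictionary
        stack = self._stack_from_rows(d, np.arange(8), (2, 2, 2))
        snr = SNRMap(np.full((2, 2, 2), 10.0), 5.0)
        snr.snr[0, 0, 0] = 2.0
        maps = match_voxels(stack, d, None, MatchConfig(), snr)
        assert maps.excluded[0, 0, 0]
        assert np.isnan(maps.r2[0, 0, 0]) and np.isnan(maps.s0[0, 0, 0])
        assert np.isfinite(maps.r2[1, 1, 1])

    def test_zero_voxel_excluded(self, small_dictionary):
        stack = np.zeros((1, 1, 1, small_dictionary.etl))
        maps = match_voxels(stack, small_dictionary, None)
        assert maps.excluded[0, 0, 0]

    def test_regularizer_shape_checked(self, small_dictionary):
        stack = np.ones((2, 2, 1, small_dictionary.etl))
        with pytest.raises(ValueError):
            match_voxels(stack, small_dictionary, np.ones((3, 3, 1)))


class TestTwoPass:
    def _setup(self, d, rng, shape=(6, 6, 1)):
        n = int(np.prod(shape))
        rows = rng.integers(0, d.n_entries, n)
        curves = d.curves[rows] * 5.0
        noisy = ncchi_sample(curves, 2, 0.02, rng=rng)
        stack = noisy.reshape(shape + (d.etl,))
        afi = B1Maps(b1_afi=np.full(shape, 100.0), zeta=np.full(shape, 0.01))
        return stack, afi

    def test_pass1_equals_unregularized_match(self, small_dictionary, rng):
        stack, afi = self._setup(small_dictionary, rng)
        cfg = MatchConfig(lam=1.0, b1_smooth_sigma=1.0)
        final, b1maps = two_pass_fit(stack, small_dictionary, afi, cfg)
        direct = match_voxels(stack, small_dictionary, None, cfg)
        # the EMC B1 input to the blend is the smoothed pass-1 map
        from emct2.b1map import smooth_emc_b1
        assert np.allclose(b1maps.b1_emc, smooth_emc_b1(direct.b1, 1.0),
                           equal_nan=True)

    def test_regularization_shrinks_b1_spread(self, small_dictionary, rng):
        """With a uniform true B1 the pass-2 B1 map varies no more than pass 1."""
        d = small_dictionary
        rows = d.row_index(50.0, 1.0) + np.zeros(36, dtype=int)
        curves = ncchi_sample(d.curves[rows] * 3.0, 2, 0.05, rng=rng)
        stack = curves.reshape(6, 6, 1, d.etl)
        afi = B1Maps(b1_afi=np.full((6, 6, 1), 100.0), zeta=np.full((6, 6, 1), 0.0))
        cfg = MatchConfig(lam=1.0, b1_smooth_sigma=1.0)
        final, _ = two_pass_fit(stack, d, afi, cfg)
        pass1 = match_voxels(stack, d, None, cfg)
        assert np.nanvar(final.b1) <= np.nanvar(pass1.b1) + 1e-12

    def test_total_cost_dominates_residual(self, small_dictionary, rng):
        stack, afi = self._setup(small_dictionary, rng)
        final, _ = two_pass_fit(stack, small_dictionary, afi, MatchConfig())
        ok = np.isfinite(final.total_cost)
        assert np.all(final.total_cost[ok] >= final.residual[ok] - 1e-15)
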