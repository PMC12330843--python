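import numpy as np
import pytest
from scipy import integrate, stats

from emct2.noise import (NoiseEstimationError, estimate_noise, ncchi_pdf,
                         ncchi_sample, noise_floor_mean, snr_map)


class TestDensity:
    def test_reduces_to_rician_at_n1(self):
        x = np.linspace(0.0, 3.0, 301)
        s, sigma = 0.8, 0.25
        ours = ncchi_pdf(x, s, 1.0, sigma)
        rice = stats.rice.pdf(x, s / sigma, scale=sigma)
        assert np.max(np.abs(ours - rice)) < 1e-12

    def test_normalizes_to_one(self):
        val, _ = integrate.quad(lambda x: ncchi_pdf(x, 1.0, 2.0, 0.1), 0.0, 3.0)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_central_limit_matches_chi(self):
        x = np.linspace(0.0, 2.0, 200)
        sigma, n = 0.3, 3.0
        ours = ncchi_pdf(x, 0.0, n, sigma)
        chi = stats.chi.pdf(x, 2 * n, scale=sigma)
        assert np.max(np.abs(ours - chi)) < 1e-12

    def test_mode_agrees_with_brute_force(self):
        s, n, sigma = 1.0, 2.0, 0.2
        x = np.linspace(0.0, 2.5, 20001)
        pdf = ncchi_pdf(x, s, n, sigma)
        x_mode = x[np.argmax(pdf)]
        # mode of a high-SNR nc-chi sits near sqrt(S^2 + (2n-1) sigma^2)
        approx = np.sqrt(s**2 + (2 * n - 1) * sigma**2)
        assert abs(x_mode - approx) < 5e-3

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            ncchi_pdf(1.0, 1.0, -1.0, 0.1)
        with pytest.raises(ValueError):
            ncchi_pdf(1.0, 1.0, 1.0, 0.0)


class TestNoiseFloor:
    def test_known_values(self):
        assert noise_floor_mean(1.0, 1.0) == pytest.approx(1.25331, abs=1e-5)
        assert noise_floor_mean(2.0, 1.0) == pytest.approx(1.87997, abs=1e-5)
        assert noise_floor_mean(2.0, 0.0) == 0.0

    def test_scales_linearly_in_sigma(self):
        assert noise_floor_mean(3.0, 2.0) == pytest.approx(2 * noise_floor_mean(3.0, 1.0))


class TestSampler:
    def test_zero_sigma_returns_signal(self):
        out = ncchi_sample(2.5, 2, 0.0, size=100, rng=0)
        assert np.all(out == 2.5)

    def test_rayleigh_mean_at_zero_signal(self, rng):
        out = ncchi_sample(0.0, 1, 1.0, size=100_000, rng=rng)
        se = out.std() / np.sqrt(out.size)
        assert abs(out.mean() - np.sqrt(np.pi / 2)) < 3 * se

    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_second_moment_identity(self, n, rng):
        s, sigma = 1.3, 0.4
        out = ncchi_sample(s, n, sigma, size=100_000, rng=rng)
        sq = out**2
        se = sq.std() / np.sqrt(sq.size)
        assert abs(sq.mean() - (s**2 + 2 * n * sigma**2)) < 3 * se

    def test_non_integer_n_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            ncchi_sample(1.0, 1.5, 0.1, size=10, rng=0)

    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            ncchi_sample(1.0, 1, 0.1, size=10)

    @pytest.mark.parametrize("snr", [0.0, 2.0, 8.0])
    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_sampler_matches_density(self, snr, n, rng):
        """KS distance between samples and the numeric CDF of the density."""
        sigma = 0.5
        s = snr * sigma
        draws = np.sort(ncchi_sample(s, n, sigma, size=100_000, rng=rng))
        grid = np.linspace(0.0, draws[-1] * 1.05, 4001)
        pdf = ncchi_pdf(grid, s, float(n), sigma)
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf_at_draws = np.interp(draws, grid, cdf)
        ks = np.max(np.abs(cdf_at_draws - (np.arange(draws.size) + 0.5) / draws.size))
        assert ks < 0.01


class TestEstimation:
    @staticmethod
    def _stack_with_background(rng, shape=(40, 40, 2, 7), n=2, sigma=10.0,
                               signal=150.0, bg_frac=0.3):
        nx, ny, nz, etl = shape
        s = np.full(shape, signal)
        n_bg = int(bg_frac * nx * ny)
        flat_idx = rng.permutation(nx * ny)[:n_bg]
        bg = np.zeros((nx, ny), dtype=bool)
        bg.ravel()[flat_idx] = True
        s[bg] = 0.0
        return ncchi_sample(s, n, sigma, rng=rng), np.repeat(bg[:, :, None], nz, 2)

    def test_recovers_known_parameters(self, rng):
        stack, _ = self._stack_with_background(rng)
        est = estimate_noise(stack)
        assert np.all(np.abs(est.sigma_eff - 10.0) / 10.0 < 0.05)
        assert np.all(np.abs(est.n_eff - 2.0) < 0.5)

    def test_pure_noise_mask_covers_almost_everything(self, rng):
        stack = ncchi_sample(np.zeros((50, 50, 1, 7)), 2, 5.0, rng=rng)
        est = estimate_noise(stack)
        assert est.background_mask.mean() > 0.99

    def test_no_background_raises(self, rng):
        stack = ncchi_sample(np.full((30, 30, 1, 7), 500.0), 2, 5.0, rng=rng)
        with pytest.raises(NoiseEstimationError):
            estimate_noise(stack)

    def test_user_mask_override(self, rng):
        stack, bg = self._stack_with_background(rng)
        est = estimate_noise(stack, background_mask=bg)
        assert np.all(np.abs(est.sigma_eff - 10.0) / 10.0 < 0.05)

    def test_bias_shrinks_with_background_size(self, rng):
        """sigma_eff error at 1e5 background samples is below that at 1e3."""
        errs = []
        for side in (12, 120):  # 1008 vs 100800 pooled samples (x7 echoes)
            stack = ncchi_sample(np.zeros((side, side, 1, 7)), 2, 10.0, rng=rng)
            est = estimate_noise(stack)
            errs.append(abs(est.sigma_eff[0] - 10.0))
        assert errs[1] < errs[0]


class TestSNRMap:
    def _est(self, nz=1, n=2.0, sigma=1.0):
        from emct2.noise import NoiseEstimate
        return NoiseEstimate(np.full(nz, n), np.full(nz, sigma),
                             np.zeros((1, 1, nz), bool))

    def test_boundary_voxel_retained_at_threshold(self):
        floor = noise_floor_mean(2.0, 1.0)
        stack = np.full((1, 2, 1, 3), 0.0)
        stack[0, 0, 0] = [5 * floor, 1.0, 0.5]   # max exactly 5x floor
        stack[0, 1, 0] = [4.99 * floor, 1.0, 0.5]
        sm = snr_map(stack, self._est(), threshold=5.0)
        assert sm.snr[0, 0, 0] == pytest.approx(5.0)
        assert not sm.exclusion_mask[0, 0, 0]   # exclusion is strict <
        assert sm.exclusion_mask[0, 1, 0]

    def test_zero_voxel_excluded(self):
        stack = np.zeros((1, 1, 1, 4))
        sm = snr_map(stack, self._est())
        assert sm.snr[0, 0, 0] == 0.0
        assert sm.exclusion_mask[0, 0, 0]

    def test_invariant_under_global_rescaling(self, rng):
        stack = rng.random((8, 8, 2, 5)) + 0.1
        est = self._est(nz=2, sigma=0.3)
        a = snr_map(stack, est).snr
        est_scaled = self._est(nz=2, sigma=0.3 * 37.0)
        b = snr_map(stack * 37.0, est_scaled).snr
        assert np.allclose(a, b, rtol=1e-12)
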