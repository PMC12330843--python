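import numpy as np
import pytest

from emct2.denoise import (DenoiseResult, PatchConfig, bias_correct,
                           denoise_and_correct, denoise_slice)
from emct2.noise import NoiseEstimate, ncchi_sample, noise_floor_mean


def _noise_est(nz, n=2.0, sigma=1.0):
    return NoiseEstimate(np.full(nz, n), np.full(nz, sigma), np.zeros((1, 1, nz), bool))


def _rank2_slice(rng, etl=7, H=16, W=16):
    """Noiseless slice whose mean-subtracted patch matrices have rank <= 2."""
    a = np.linspace(1.0, 2.0, H)[None, :, None]
    b = np.linspace(0.5, 1.5, W)[None, None, :]
    c1 = np.exp(-np.arange(etl) / 3.0)[:, None, None]
    c2 = np.exp(-np.arange(etl) / 9.0)[:, None, None]
    return c1 * a + c2 * b


class TestPatchConfig:
    def test_default_for_seven_echoes(self):
        cfg = PatchConfig.for_etl(7)
        assert cfg.patch_size == 3 and cfg.rank == 2

    @pytest.mark.parametrize("kwargs", [
        {"patch_size": 1}, {"rank": 0}, {"stride": 0}, {"weighting": "magic"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PatchConfig(**kwargs)


class TestDenoiseSlice:
    def test_rank2_data_passes_through(self, rng):
        sl = _rank2_slice(rng)
        est, w, origins = denoise_slice(sl, PatchConfig())
        # every filtered patch must equal the original patch content
        ys, xs = origins
        for iy in (0, len(ys) // 2, -1):
            for ix in (0, len(xs) // 2, -1):
                y, x = ys[iy], xs[ix]
                assert np.allclose(est[iy, ix], sl[:, y:y + 3, x:x + 3], atol=1e-6)

    def test_noise_variance_reduced(self, rng):
        """Rank-2-of-7 filtering plus sliding-window averaging shrinks the
        noise variance of a pure-noise slice substantially."""
        stack = ncchi_sample(np.zeros((32, 32, 1, 7)), 2, 1.0, rng=rng)
        res = denoise_and_correct(stack, _noise_est(1, 2, 1.0))
        assert res.denoised.var() < 0.7 * stack.var()

    def test_single_echo_rejected(self):
        with pytest.raises(ValueError):
            denoise_slice(np.zeros((1, 8, 8)), PatchConfig())

    def test_slice_smaller_than_patch_rejected(self):
        with pytest.raises(ValueError):
            denoise_slice(np.zeros((7, 2, 2)), PatchConfig(patch_size=3))


class TestBiasCorrect:
    def test_clipping_branch_flagged(self):
        sq = np.full((3, 4, 4), 1.0)
        w = np.ones((4, 4))
        out, clipped = bias_correct(sq, w, n_eff=2.0, sigma_eff=1.0)  # 2*n*s^2 = 4 > 1
        assert np.all(out == 0.0)
        assert np.all(clipped)

    def test_noiseless_limit_is_pure_aggregation(self):
        sq = np.full((3, 4, 4), 9.0)
        out, clipped = bias_correct(sq, np.ones((4, 4)), 2.0, 0.0)
        assert np.allclose(out, 3.0)
        assert not clipped.any()

    def test_second_moment_identity_recovers_signal(self, rng):
        """E[x^2] = S^2 + 2 n sigma^2: subtracting the offset from raw squared
        samples recovers S^2 within 2% at 1e4 voxels (exact-identity oracle)."""
        S, n, sigma = 30.0, 2, 10.0
        vol = ncchi_sample(np.full((7, 100, 100), S), n, sigma, rng=rng)
        out, _ = bias_correct(vol**2, np.ones((100, 100)), n, sigma)
        assert np.mean(out**2) == pytest.approx(S**2, rel=0.02)

    def test_uncovered_voxels_rejected(self):
        with pytest.raises(ValueError):
            bias_correct(np.ones((3, 4, 4)), np.zeros((4, 4)), 2.0, 1.0)


class TestDenoiseAndCorrect:
    def test_idempotent_on_rank2_noiseless_data(self, rng):
        sl = _rank2_slice(rng)
        stack = sl.transpose(1, 2, 0)[:, :, None, :]
        est = _noise_est(1, sigma=0.0)
        once = denoise_and_correct(stack, est)
        twice = denoise_and_correct(once.corrected, est)
        assert np.max(np.abs(twice.corrected - once.corrected)) < 1e-6

    def test_preserves_shape_and_order(self, rng):
        stack = rng.random((10, 12, 2, 7)) + 1.0
        res = denoise_and_correct(stack, _noise_est(2, sigma=0.0))
        assert res.corrected.shape == stack.shape
        assert isinstance(res, DenoiseResult)
        # echo ordering preserved: monotone input stays monotone after
        # noiseless filtering on rank-deficient data
        const = np.ones((8, 8, 1, 1)) * np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.25])
        out = denoise_and_correct(const, _noise_est(1, sigma=0.0)).corrected
        assert np.all(np.diff(out[4, 4, 0]) < 0)

    def test_background_floor_reduced_after_correction(self, rng):
        """At S = 0 the correction removes most of the magnitude floor.

        The residue is the variance the rank-P patch estimates retain; at the
        default l = 3 (M = ETL) about a quarter of the floor survives, and
        larger patches push it below 20%.
        """
        n, sigma = 2, 1.0
        stack = ncchi_sample(np.zeros((48, 48, 1, 7)), n, sigma, rng=rng)
        raw_floor = noise_floor_mean(n, sigma)
        res = denoise_and_correct(stack, _noise_est(1, n, sigma))
        assert np.mean(res.corrected) < 0.3 * raw_floor
        res5 = denoise_and_correct(stack, _noise_est(1, n, sigma),
                                   PatchConfig(patch_size=5))
        assert np.mean(res5.corrected) < 0.2 * raw_floor

    def test_pca_alone_preserves_mean_bias(self, rng):
        """The PCA step does not remove the magnitude offset; only the
        bias-correction term does."""
        n, sigma = 2, 1.0
        stack = ncchi_sample(np.zeros((40, 40, 1, 7)), n, sigma, rng=rng)
        res = denoise_and_correct(stack, _noise_est(1, n, sigma))
        floor = noise_floor_mean(n, sigma)
        se = stack.std() / np.sqrt(stack.size / 9)  # patches overlap 9x
        assert abs(res.denoised.mean() - floor) < 4 * se

    def test_rmse_improves_on_decaying_signal(self, rng):
        """Denoise + bias-correct beats the raw stack against ground truth."""
        n, sigma = 2, 1.0
        truth_curve = 12.0 * np.exp(-np.arange(7) * 9.0 / 50.0)  # SNR ~ 6.4
        truth = np.broadcast_to(truth_curve, (24, 24, 1, 7))
        noisy = ncchi_sample(truth, n, sigma, rng=rng)
        res = denoise_and_correct(noisy, _noise_est(1, n, sigma))
        rmse_raw = np.sqrt(np.mean((noisy - truth)**2))
        rmse_corr = np.sqrt(np.mean((res.corrected - truth)**2))
        assert rmse_corr < rmse_raw

    def test_missing_slice_estimate_rejected(self, rng):
        stack = rng.random((8, 8, 3, 7))
        with pytest.raises(ValueError):
            denoise_and_correct(stack, _noise_est(2))
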