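"""Image formation y = H*x + n + b: projection, noise, SNR fitting."""

import numpy as np
import pytest
from scipy import ndimage

from flfm import (LFImage, NoiseParams, PSFStack, Volume, corrupt,
                  fit_noise_to_target, forward_project, measure_snr)
from flfm.forward import measure_sbr


def synthetic_psf_stack(n_depth=41, sensor=64, ksize=21, seed=0):
    """A small random nonnegative PSF stack for convolution oracles."""
    rng = np.random.default_rng(seed)
    full = np.zeros((n_depth, sensor, sensor))
    c = sensor // 2
    half = ksize // 2
    for z in range(n_depth):
        k = rng.random((ksize, ksize))
        full[z, c - half:c + half + 1, c - half:c + half + 1] = k / k.sum()
    return PSFStack(full=full, depth_values_um=np.linspace(-3.5, 3.5, n_depth),
                    pixel_pitch_um=6.5)


class TestForwardProject:
    def test_zero_volume_gives_zero_lf(self, cfg, psf, voxel_nm):
        v = Volume(np.zeros((cfg.depth_planes, 32, 32)), voxel_nm)
        lf = forward_project(v, psf)
        assert not lf.data.any()

    def test_centered_impulse_reproduces_psf_plane(self, cfg, psf, voxel_nm):
        D = cfg.depth_planes
        for iz in (0, D // 2, D - 1):
            data = np.zeros((D, 64, 64))
            data[iz, 32, 32] = 1.0
            lf = forward_project(Volume(data, voxel_nm), psf)
            np.testing.assert_allclose(lf.data, psf.full[iz], atol=1e-12)

    def test_agrees_with_direct_convolution_oracle(self):
        """FFT projection vs scipy's direct spatial convolution on a
        dense random 32x32x41 volume."""
        psf = synthetic_psf_stack()
        rng = np.random.default_rng(1)
        x = rng.random((41, 32, 32))
        vol = Volume(x, (175.0, 162.5, 162.5))
        got = forward_project(vol, psf).data
        sensor = psf.full.shape[1]
        pad = np.zeros((41, sensor, sensor))
        pad[:, 16:48, 16:48] = x
        expected = np.zeros((sensor, sensor))
        for z in range(41):
            expected += ndimage.convolve(pad[z], psf.full[z],
                                         mode="constant", origin=0)
        rel = np.abs(got - expected).max() / expected.max()
        assert rel < 1e-6

    def test_linearity(self, cfg, psf, voxel_nm):
        rng = np.random.default_rng(2)
        a = Volume(rng.random((cfg.depth_planes, 32, 32)), voxel_nm)
        b = Volume(rng.random((cfg.depth_planes, 32, 32)), voxel_nm)
        ab = Volume(a.data + b.data, voxel_nm)
        lhs = forward_project(ab, psf).data
        rhs = forward_project(a, psf).data + forward_project(b, psf).data
        assert np.abs(lhs - rhs).max() / rhs.max() < 1e-6

    def test_grid_mismatch_raises(self, psf, voxel_nm):
        with pytest.raises(ValueError, match="axis z"):
            forward_project(Volume(np.ones((5, 8, 8)), voxel_nm), psf)
        with pytest.raises(ValueError, match="axis y/x"):
            forward_project(Volume(np.ones((41, 500, 500)), voxel_nm), psf)


class TestCorrupt:
    def test_background_only_is_exact_shift(self):
        clean = LFImage(np.arange(16.0).reshape(4, 4))
        noisy = corrupt(clean, NoiseParams(background=5.0))
        np.testing.assert_array_equal(noisy.data, clean.data + 5.0)

    def test_fixed_seed_bit_identical(self):
        clean = LFImage(np.full((32, 32), 3.0))
        p = NoiseParams(poisson_gain=10.0, gaussian_sigma=0.5,
                        background=1.0, seed=42)
        np.testing.assert_array_equal(corrupt(clean, p).data,
                                      corrupt(clean, p).data)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            corrupt(np.array([[-1.0, 0.0]]), NoiseParams())

    def test_moments_match_poisson_gaussian_model(self):
        """Monte-Carlo over 10^4 seeded draws of corrupt() on a 64x64
        constant image: per-pixel sample mean within 3 standard errors
        of clean + b, sample variance within 10% of clean/gain +
        sigma^2 (expectation pre-clipping equals clean + b)."""
        level, gain, sigma, b = 20.0, 4.0, 0.8, 2.0
        clean = LFImage(np.full((64, 64), level))
        n_draws = 10_000
        s = np.zeros((64, 64))
        s2 = np.zeros((64, 64))
        for seed in range(n_draws):
            d = corrupt(clean, NoiseParams(poisson_gain=gain,
                                           gaussian_sigma=sigma,
                                           background=b, seed=seed)).data
            s += d
            s2 += d * d
        mean = s / n_draws
        var = s2 / n_draws - mean**2
        target_var = level / gain + sigma**2
        se = np.sqrt(target_var / n_draws)
        # ~0.27% of pixels are expected beyond 3 SE by chance alone
        frac_beyond = np.mean(np.abs(mean - (level + b)) > 3 * se)
        assert frac_beyond < 0.01
        assert abs(mean.mean() - (level + b)) < 3 * se / 64
        assert abs(var.mean() - target_var) / target_var < 0.10


class TestFitNoise:

    def test_realizes_low_snr_regime(self, tube_lf):
        """The study's hardest regime: -1.62 dB realized within 0.5 dB."""
        params = fit_noise_to_target(tube_lf, -1.62, seed=0)
        realized = measure_snr(tube_lf.data + params.background,
                               corrupt(tube_lf, NoiseParams(
                                   poisson_gain=params.poisson_gain,
                                   gaussian_sigma=params.gaussian_sigma,
                                   background=params.background,
                                   seed=999)).data)
        assert realized == pytest.approx(-1.62, abs=0.5)

    def test_high_snr_limit_small_sigma(self, tube_lf):
        p_hi = fit_noise_to_target(tube_lf, 40.0, seed=0)
        p_lo = fit_noise_to_target(tube_lf, 0.0, seed=0)
        assert p_hi.gaussian_sigma < 0.05 * p_lo.gaussian_sigma
        assert p_hi.poisson_gain > p_lo.poisson_gain

    def test_sigma_monotone_in_target(self, tube_lf):
        gains = 50.0
        sigmas = [fit_noise_to_target(tube_lf, t, poisson_gain=gains,
                                      seed=0).gaussian_sigma
                  for t in (6.0, 2.0, -2.0)]
        assert sigmas[0] < sigmas[1] < sigmas[2]

    def test_sbr_target_honored(self, tube_lf):
        from skimage.filters import threshold_otsu
        params = fit_noise_to_target(tube_lf, 10.0, target_sbr=2.0, seed=0)
        mask = tube_lf.data > threshold_otsu(tube_lf.data)
        sbr = measure_sbr(tube_lf.data + params.background, mask)
        assert sbr == pytest.approx(2.0, rel=0.05)

    def test_infeasible_targets_rejected(self, tube_lf):
        with pytest.raises(ValueError):
            fit_noise_to_target(tube_lf, np.inf, seed=0)
        with pytest.raises(ValueError):
            fit_noise_to_target(tube_lf, 10.0, target_sbr=0.5, seed=0)
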