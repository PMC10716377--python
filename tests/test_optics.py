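"""Wave-optics PSF: DOE phase, sub-image geometry, energy, parallax."""

import numpy as np
import pytest
from scipy import ndimage

from flfm.optics import (ConfigurationError, OpticalConfig, SamplingError,
                         compute_psf, desk_scale_config, doe_phase, psf_views,
                         _fourier_grid)


class TestOpticalConfig:
    def test_default_matches_instrument_constants(self):
        cfg = OpticalConfig()
        assert cfg.f_number == pytest.approx(120.0 / 3.25, rel=1e-6)
        assert cfg.lateral_sampling_nm == pytest.approx(162.5)
        assert cfg.total_magnification == pytest.approx(40.0)
        assert len(cfg.depth_values_um) == 41
        assert cfg.depth_values_um[20] == 0.0
        np.testing.assert_allclose(cfg.depth_values_um,
                                   -cfg.depth_values_um[::-1])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            OpticalConfig(numerical_aperture=1.6)          # NA above index
        with pytest.raises(ConfigurationError):
            OpticalConfig(depth_planes=40)                 # no z = 0 plane
        with pytest.raises(ConfigurationError):
            OpticalConfig(f_number=20.0)                   # f_ML/d mismatch
        with pytest.raises(ConfigurationError):            # overlapping lenslets
            OpticalConfig(lenslet_centers_mm=[[0, 1.0], [0, -1.0], [1.0, 0]])

    def test_lenslet_apertures_inside_pupil(self, cfg):
        r_ap = cfg.lenslet_pitch_mm / 2
        for c in cfg.lenslet_centers_mm:
            assert np.hypot(*c) + r_ap <= cfg.pupil_radius_m * 1e3 + 1e-9


class TestDOEPhase:
    def test_vertex_zero_and_symmetry(self, cfg):
        n = 240
        phase = doe_phase(cfg, n)
        V, U, du = _fourier_grid(cfg, n)
        for cx, cy in cfg.lenslet_centers_mm * 1e-3:
            i = n // 2 - int(round(cy / du))   # y -> -row
            j = n // 2 + int(round(cx / du))
            # vertex of the quadratic profile: phase ~ 0 (mod 2 pi)
            p = phase[i, j]
            assert min(p, 2 * np.pi - p) < 1e-2
        # 120-degree symmetry of the equilateral triple: rotating the
        # lenslet centres by 120 degrees permutes them, so the phase map
        # is unchanged (checked analytically, no interpolation)
        th = np.deg2rad(120.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cfg_rot = cfg.scaled_copy(
            lenslet_centers_mm=cfg.lenslet_centers_mm @ R.T)
        np.testing.assert_allclose(doe_phase(cfg_rot, n), phase, atol=1e-6)

    def test_radial_profile_matches_thin_lens(self, cfg):
        n = 400
        phase = doe_phase(cfg, n)
        V, U, du = _fourier_grid(cfg, n)
        cx, cy = cfg.lenslet_centers_mm[0] * 1e-3
        r2 = (U - cx) ** 2 + (V + cy) ** 2
        mask = r2 <= (cfg.lenslet_pitch_mm * 1e-3 / 2) ** 2
        lam_f = cfg.wavelength_m * cfg.lenslet_focal_mm * 1e-3
        expected = np.mod(-np.pi * r2[mask] / lam_f, 2 * np.pi)
        np.testing.assert_allclose(phase[mask], expected, atol=1e-6)


class TestPSF:
    def test_three_maxima_at_geometric_positions(self, cfg, psf):
        z0 = psf.full[cfg.depth_planes // 2]
        lab, n = ndimage.label(z0 > 0.25 * z0.max())
        assert n == 3
        coms = np.asarray(ndimage.center_of_mass(z0, lab, range(1, 4)))
        for g in cfg.view_centers_px:
            assert np.min(np.hypot(*(coms - g).T)) <= 1.0
        # equilateral arrangement: pairwise distances equal within 1 px
        d = [np.hypot(*(coms[i] - coms[j])) for i in range(3)
             for j in range(i + 1, 3)]
        assert max(d) - min(d) <= 1.0

    def test_energy_conserved_across_depth(self, psf):
        e = psf.energy_per_depth()
        assert (e.max() - e.min()) / e.mean() < 0.05

    def test_nonnegative_and_normalized(self, cfg, psf):
        assert np.all(psf.full >= 0)
        assert psf.full[cfg.depth_planes // 2].sum() == pytest.approx(1.0)

    def test_centroid_shift_linear_with_depth(self, cfg, psf, cal):
        """Parallax: per-view centroid moves linearly in z with opposite
        slopes for opposed lenslets, matching the geometric prediction."""
        kern = psf_views(psf, cal)
        zs = cfg.depth_values_um
        pred = cfg.parallax_slope_px_per_um()
        slopes = []
        for v in range(3):
            cents = np.array([ndimage.center_of_mass(kern[iz, v])
                              for iz in range(len(zs))])
            # project displacement on the predicted parallax direction
            direction = pred[v] / np.linalg.norm(pred[v])
            proj = (cents - cents.mean(axis=0)) @ direction
            p = np.polyfit(zs, proj, 1)
            resid = proj - np.polyval(p, zs)
            r2 = 1 - np.sum(resid**2) / np.sum((proj - proj.mean()) ** 2)
            assert r2 > 0.99
            slopes.append(p[0] * direction)
        slopes = np.asarray(slopes)
        # prediction within 10%
        np.testing.assert_allclose(np.hypot(*slopes.T), np.hypot(*pred.T),
                                   rtol=0.10)
        # opposed lenslets move in opposite senses
        assert np.dot(slopes[0], slopes[1]) < 0 or np.dot(slopes[0], slopes[2]) < 0
        assert np.allclose(slopes.sum(axis=0), 0, atol=0.2 * np.abs(slopes).max())

    def test_no_wraparound_aliasing_and_grid_convergence(self):
        """Circular wrap-around would deposit energy at the FFT window
        border; with the sampling criterion satisfied the border is
        empty and refining the grid only perturbs the PSF marginally."""
        cfg = desk_scale_config()
        n = cfg.fft_grid
        full_cfg = desk_scale_config(sensor_grid=(n, n))
        window = compute_psf(full_cfg).full
        border = np.concatenate([window[:, :4, :].ravel(),
                                 window[:, -4:, :].ravel(),
                                 window[:, :, :4].ravel(),
                                 window[:, :, -4:].ravel()])
        # hard-aperture diffraction tails legitimately carry ~1e-4 of
        # the energy out to the window border; wrap-around would add far
        # more
        assert border.sum() < 1e-3 * window.sum()
        a = compute_psf(desk_scale_config(sensor_grid=(160, 160))).full
        b = compute_psf(desk_scale_config(sensor_grid=(160, 160),
                                          fft_grid=800)).full
        assert np.max(np.abs(a - b)) / np.max(a) < 1e-2

    def test_undersampled_grid_raises_with_depth(self):
        cfg = desk_scale_config(fft_grid=256)
        with pytest.raises(SamplingError, match="um"):
            compute_psf(cfg)


class TestPSFViews:
    def test_views_partition_full_psf(self, psf, cal, kernels):
        from flfm.geometry import ViewStack, assemble_lf
        h, w = cal.view_size
        for iz in [0, psf.n_depths // 2, psf.n_depths - 1]:
            asm = assemble_lf(ViewStack(kernels[iz]), cal,
                              sensor_grid=psf.full.shape[1:])
            # crops reproduce the full PSF exactly inside the windows
            mask = asm.data > 0
            np.testing.assert_array_equal(asm.data[mask],
                                          psf.full[iz][mask])
            assert kernels[iz].sum() == pytest.approx(asm.data.sum())
        # view windows capture nearly all sensor energy
        assert kernels.sum() / psf.full.sum() > 0.95

    def test_z0_views_congruent_up_to_symmetry(self, psf, cal, kernels):
        """The on-axis sub-PSFs are congruent under the 120-degree
        arrangement symmetry: their cumulative radial energy
        distributions agree within 1% RMS (insensitive to the sub-pixel
        crop offsets of the three windows)."""
        from scipy import fft as sfft

        def upsample4(img):
            # exact for the band-limited intensity PSF
            n = img.shape[0]
            F = sfft.fftshift(sfft.fft2(img))
            pad = np.zeros((4 * n, 4 * n), complex)
            c = 2 * n
            pad[c - n // 2:c + n // 2, c - n // 2:c + n // 2] = F
            return np.maximum(np.real(sfft.ifft2(sfft.ifftshift(pad))), 0)

        z0 = kernels[psf.n_depths // 2]
        h = z0.shape[1] * 4
        yy, xx = np.indices((h, h))
        r_grid = np.linspace(0.5, h / 2 - 1, 120)
        curves = []
        for v in range(3):
            u = upsample4(z0[v])
            com = ndimage.center_of_mass(u)
            r = np.hypot(yy - com[0], xx - com[1]).ravel()
            order = np.argsort(r)
            cum = np.cumsum(u.ravel()[order])
            cum /= cum[-1]
            curves.append(np.interp(r_grid, r[order], cum))
        for v in (1, 2):
            rms = np.sqrt(np.mean((curves[v] - curves[0]) ** 2))
            assert rms < 0.01

    def test_crop_window_bounds_checked(self, psf, cfg):
        from flfm.geometry import CalibrationResult
        bad = CalibrationResult(rotation_degrees=0.0,
                                view_centers=psf.config.view_centers_px,
                                view_size=(300, 300))
        with pytest.raises(ValueError, match="exceeds sensor"):
            psf_views(psf, bad)
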