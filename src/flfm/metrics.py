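"""Quantitative evaluation: SNR, SSIM, NRMSE, error maps, spectral resolution.

The SNR follows the log-ratio definition

    SNR = 10 * log10( sum (f - fbar)^2 / sum (fhat - f)^2 )

with ``f`` the reference signal, ``fhat`` the noisy image and ``fbar``
the mean of ``f`` over the grid.

SSIM uses the standard windowed formulation (uniform 7x7(x7) window,
K1 = 0.01, K2 = 0.03) via scikit-image; NRMSE is the RMSE normalized by
the reference dynamic range.  Both are computed after min-max
normalization of both images by the *reference's* range, which matters
and is therefore stated here: with reference range [lo, hi], each image
is mapped through (v - lo) / (hi - lo) before comparison.

Resolution is estimated from the radially averaged power spectrum: the
noise floor is the mean spectral power over the highest-frequency decile
of radii, the cutoff is the lowest frequency at which the (lightly
smoothed) spectrum falls to floor + 0.5% of the floor-to-peak excursion,
and resolution = 1 / cutoff.  If no significant power sits above the
floor, or the spectrum never reaches it below Nyquist, the sampling
limit (2 pixels) is returned with ``limited=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity as _sk_ssim


@dataclass
class MetricsRecord:
    snr_db: float | None = None
    ssim: float | None = None
    nrmse: float | None = None
    lateral_resolution_nm: float | None = None
    axial_resolution_nm: float | None = None


def measure_snr(reference: np.ndarray, noisy: np.ndarray) -> float:
    """Signal-to-noise ratio in dB of ``noisy`` against ``reference``."""
    f = np.asarray(reference, dtype=np.float64)
    fhat = np.asarray(noisy, dtype=np.float64)
    if f.shape != fhat.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {fhat.shape}")
    signal = np.sum((f - f.mean()) ** 2)
    if signal == 0:
        raise ValueError("SNR undefined for a constant reference")
    noise = np.sum((fhat - f) ** 2)
    if noise == 0:
        return np.inf
    return float(10.0 * np.log10(signal / noise))


def _normalize_pair(reference: np.ndarray, other: np.ndarray):
    lo, hi = float(reference.min()), float(reference.max())
    if hi <= lo:
        raise ValueError("constant reference: normalization undefined")
    scale = hi - lo
    return (reference - lo) / scale, (other - lo) / scale


def ssim(reference: np.ndarray, image: np.ndarray,
         win_size: int = 7) -> float:
    """Windowed SSIM after min-max normalization on the reference range."""
    a, b = _normalize_pair(np.asarray(reference, float),
                           np.asarray(image, float))
    return float(_sk_ssim(a, b, win_size=win_size, data_range=1.0,
                          gaussian_weights=False))


def nrmse(reference: np.ndarray, image: np.ndarray) -> float:
    """RMSE normalized by the reference dynamic range."""
    f = np.asarray(reference, dtype=np.float64)
    g = np.asarray(image, dtype=np.float64)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {g.shape}")
    rng = f.max() - f.min()
    if rng == 0:
        raise ValueError("constant reference: NRMSE undefined")
    return float(np.sqrt(np.mean((f - g) ** 2)) / rng)


def error_map(gt: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Per-voxel |gt - pred| after normalizing both by gt's min-max range."""
    a, b = _normalize_pair(np.asarray(gt, float), np.asarray(pred, float))
    return np.abs(a - b)


def localize_peak(volume: np.ndarray, near: np.ndarray,
                  radius: int = 6) -> np.ndarray:
    """Sub-voxel 3D peak localization by 3-point parabolic interpolation.

    Searches the window of ``radius`` voxels around ``near`` for the
    intensity maximum and refines each axis with a parabola through the
    peak and its two neighbours — the standard sub-voxel estimator for
    bead localization, insensitive to asymmetric tails.
    """
    vol = np.asarray(volume, dtype=np.float64)
    zi, yi, xi = np.rint(np.asarray(near)).astype(int)
    sl = tuple(slice(max(c - radius, 0), min(c + radius + 1, n))
               for c, n in zip((zi, yi, xi), vol.shape))
    win = vol[sl]
    p = np.array(np.unravel_index(np.argmax(win), win.shape))
    out = []
    for ax in range(3):
        i = p[ax]
        if 0 < i < win.shape[ax] - 1:
            idx = list(p)

            def val(k, idx=idx, ax=ax):
                idx2 = list(idx)
                idx2[ax] = k
                return win[tuple(idx2)]

            y0, y1, y2 = val(i - 1), val(i), val(i + 1)
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-30 else 0.0
            delta = float(np.clip(delta, -1.0, 1.0))
        else:
            delta = 0.0
        out.append(i + delta + sl[ax].start)
    return np.asarray(out)


def radial_power_spectrum(image: np.ndarray):
    """Radially averaged power spectrum; returns (freq cycles/px, power)."""
    img = np.asarray(image, dtype=np.float64)
    img = img - img.mean()
    spec = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
    h, w = img.shape
    fy = np.fft.fftshift(np.fft.fftfreq(h))
    fx = np.fft.fftshift(np.fft.fftfreq(w))
    FR = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    nbins = min(h, w) // 2
    edges = np.linspace(0, 0.5, nbins + 1)
    idx = np.clip(np.digitize(FR.ravel(), edges) - 1, 0, nbins - 1)
    power = np.bincount(idx, weights=spec.ravel(), minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    power = power / np.maximum(counts, 1)
    freq = 0.5 * (edges[:-1] + edges[1:])
    return freq, power


def resolution_from_spectrum(image: np.ndarray, pixel_size_nm: float,
                             floor_decile: float = 0.1,
                             rel_threshold: float = 0.005):
    """Estimate spatial resolution (nm) from the image power spectrum.

    Returns ``(resolution_nm, limited)`` where ``limited`` flags a
    degenerate estimate clamped at the two-pixel sampling limit.
    """
    if min(image.shape) < 16:
        raise ValueError("image too small for spectral resolution analysis")
    freq, power = radial_power_spectrum(image)
    power = ndimage.uniform_filter1d(power, size=3)
    n_floor = max(2, int(np.ceil(floor_decile * len(power))))
    floor = float(np.mean(power[-n_floor:]))
    # skip the DC-dominated first bins
    body = power[2:]
    peak = float(body.max())
    if peak <= 3.0 * max(floor, 1e-300):
        return 2.0 * pixel_size_nm, True
    thresh = floor + rel_threshold * (peak - floor)
    below = np.nonzero(body <= thresh)[0]
    if len(below) == 0:
        return 2.0 * pixel_size_nm, True
    cutoff = freq[2 + below[0]]                 # cycles per pixel
    if cutoff <= 0:
        return 2.0 * pixel_size_nm, True
    res = pixel_size_nm / cutoff
    return float(max(res, 2.0 * pixel_size_nm)), False
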