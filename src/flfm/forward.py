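"""Image formation: y = H*x + n + b.

A clean light field is the depthwise convolution of the sample volume
with the per-depth PSF, summed over depth; the recorded frame adds shot
noise, read noise and a constant camera background:

    y = sum_z (x_z (*) H_z) + n + b

Noise order follows the physical sequence: Poisson shot noise on the
clean intensity (with ``poisson_gain`` photons per intensity unit), then
additive Gaussian read noise, then the constant background, with a final
clip at zero (the camera output after offset subtraction is
nonnegative).  Convolutions are FFT-based with explicit zero-padding so
no circular wrap-around occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from skimage.filters import threshold_otsu

from .geometry import LFImage
from .metrics import measure_snr
from .optics import PSFStack


@dataclass
class Volume:
    """A 3D nonnegative intensity grid (z, y, x) with voxel metadata."""

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float]      # (dz, dy, dx)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D (z, y, x)")
        if np.any(self.data < 0):
            raise ValueError("Volume intensities must be nonnegative")


@dataclass
class NoiseParams:
    """Shot/read-noise and background parameters of the camera model."""

    poisson_gain: float = 0.0        # photons per intensity unit; 0 disables
    gaussian_sigma: float = 0.0      # intensity units
    background: float = 0.0          # intensity units
    seed: int = 0

    def __post_init__(self):
        if self.poisson_gain < 0 or self.gaussian_sigma < 0 or self.background < 0:
            raise ValueError("noise parameters must be nonnegative")

    def to_dict(self) -> dict:
        return {"poisson_gain": float(self.poisson_gain),
                "gaussian_sigma": float(self.gaussian_sigma),
                "background": float(self.background),
                "seed": int(self.seed)}


def forward_project(volume: Volume, psf: PSFStack) -> LFImage:
    """Clean light field sum_z (x_z (*) H_z) on the sensor grid.

    The volume's lateral grid must use the sensor-referred sampling and
    be no larger than the sensor; it is centred on the sensor before
    convolution.
    """
    x = volume.data
    if x.shape[0] != psf.n_depths:
        raise ValueError(
            f"axis z: volume has {x.shape[0]} planes, PSF has {psf.n_depths}")
    gh, gw = psf.full.shape[1:]
    if x.shape[1] > gh or x.shape[2] > gw:
        raise ValueError(
            f"axis y/x: volume lateral size {x.shape[1:]} exceeds sensor "
            f"({gh}, {gw})")
    pad = np.zeros((x.shape[0], gh, gw))
    r0 = (gh - x.shape[1]) // 2
    c0 = (gw - x.shape[2]) // 2
    pad[:, r0:r0 + x.shape[1], c0:c0 + x.shape[2]] = x
    # linear convolution on a zero-padded grid; the PSF origin is the
    # optical-axis pixel (gh//2, gw//2), so crop with that offset
    lh = sfft.next_fast_len(2 * gh)
    lw = sfft.next_fast_len(2 * gw)
    acc = np.zeros((lh, lw // 2 + 1), dtype=complex)
    for z in range(psf.n_depths):
        if not pad[z].any():
            continue
        acc += sfft.rfft2(pad[z], s=(lh, lw)) * _otf(psf, z, (lh, lw))
    full = sfft.irfft2(acc, s=(lh, lw))
    out = full[gh // 2:gh // 2 + gh, gw // 2:gw // 2 + gw]
    return LFImage(data=np.maximum(out, 0.0),
                   pixel_pitch_um=psf.pixel_pitch_um)


def _otf(psf: PSFStack, z: int, shape: tuple[int, int]) -> np.ndarray:
    """Cached rFFT of depth plane ``z`` of the PSF at padded ``shape``."""
    cache = getattr(psf, "_otf_cache", None)
    if cache is None or cache[0] != shape:
        cache = (shape, {})
        psf._otf_cache = cache
    if z not in cache[1]:
        cache[1][z] = sfft.rfft2(psf.full[z], s=shape)
    return cache[1][z]


def corrupt(clean: LFImage | np.ndarray, params: NoiseParams) -> LFImage:
    """Apply Poisson + Gaussian noise and constant background, clip at 0."""
    data = clean.data if isinstance(clean, LFImage) else np.asarray(clean, float)
    if np.any(data < 0):
        raise ValueError("clean input must be nonnegative")
    rng = np.random.default_rng(params.seed)
    if params.poisson_gain > 0:
        out = rng.poisson(params.poisson_gain * data).astype(np.float64) \
            / params.poisson_gain
    else:
        out = data.copy()
    if params.gaussian_sigma > 0:
        out += rng.normal(0.0, params.gaussian_sigma, size=out.shape)
    out += params.background
    out = np.maximum(out, 0.0)
    pitch = clean.pixel_pitch_um if isinstance(clean, LFImage) else 1.0
    return LFImage(data=out, pixel_pitch_um=pitch)


def measure_sbr(image: np.ndarray, foreground_mask: np.ndarray) -> float:
    """mean(foreground) / mean(background) for a given foreground mask."""
    fg = image[foreground_mask]
    bg = image[~foreground_mask]
    if fg.size == 0 or bg.size == 0:
        raise ValueError("degenerate foreground mask")
    mbg = bg.mean()
    if mbg <= 0:
        return np.inf
    return float(fg.mean() / mbg)


def fit_noise_to_target(clean: LFImage, target_snr_db: float,
                        target_sbr: float | None = None,
                        poisson_gain: float | None = None,
                        seed: int = 0, max_iter: int = 40) -> NoiseParams:
    """Find noise parameters realizing a measured SNR (and optionally SBR).

    Procedure (deterministic under ``seed``):

    1. the background ``b`` solves the SBR equation in closed form,
       with foreground = pixels above the Otsu threshold of the clean LF
       (SBR = mean(fg)/mean(bg) evaluated on clean + b);
    2. the Poisson gain is set so shot noise contributes half the target
       noise power (unless given explicitly);
    3. the Gaussian sigma is found by bisection on the SNR measured on an
       actual seeded corruption, which accounts for the zero-clipping.
    """
    f0 = clean.data
    if f0.max() <= 0 or np.all(f0 == f0.flat[0]):
        raise ValueError("clean LF has no signal")
    if not np.isfinite(target_snr_db) or target_snr_db > 60.0:
        raise ValueError(
            f"target SNR {target_snr_db} dB exceeds the supported noiseless "
            "limit (60 dB)")

    # -- background from SBR --------------------------------------------
    b = 0.0
    if target_sbr is not None:
        mask = f0 > threshold_otsu(f0)
        mu_f, mu_b = f0[mask].mean(), f0[~mask].mean()
        raw = measure_sbr(f0, mask)
        if target_sbr <= 1.0:
            raise ValueError("target SBR must exceed 1")
        if target_sbr > raw:
            raise ValueError(
                f"target SBR {target_sbr:.2f} exceeds the background-free "
                f"ratio {raw:.2f}")
        b = (mu_f - target_sbr * mu_b) / (target_sbr - 1.0)
        b = max(b, 0.0)

    f = f0 + b
    signal = np.sum((f - f.mean()) ** 2)
    noise_target = signal / 10.0 ** (target_snr_db / 10.0)

    if poisson_gain is None:
        total = f0.sum()
        poisson_gain = max(2.0 * total / noise_target, 1e-12)

    def realized(sigma: float) -> float:
        p = NoiseParams(poisson_gain=poisson_gain, gaussian_sigma=sigma,
                        background=b, seed=seed)
        return measure_snr(f, corrupt(clean, p).data)

    sigma0 = np.sqrt(noise_target / f0.size)
    lo, hi = 0.0, max(4.0 * sigma0, 1e-9)
    if realized(lo) < target_snr_db - 0.05:
        raise ValueError(
            f"target SNR {target_snr_db} dB infeasible: shot noise alone "
            f"gives {realized(lo):.2f} dB")
    while realized(hi) > target_snr_db and hi < 1e6 * sigma0:
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if realized(mid) > target_snr_db:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6 * max(hi, 1e-12):
            break
    sigma = 0.5 * (lo + hi)
    return NoiseParams(poisson_gain=poisson_gain, gaussian_sigma=sigma,
                       background=b, seed=seed)
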