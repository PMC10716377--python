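# flfm — Fourier light-field microscopy simulation and reconstruction

`flfm` is a toolkit for **Fourier light-field microscopy** (FLFM): a
single-shot 3D fluorescence imaging modality in which a lenslet triple in
a pupil-conjugate (Fourier) plane splits the light into three perspective
views recorded side by side in one camera frame. Because an emitter's
axial position appears as lateral disparity between the views, a whole
volume (41 planes over ~7 µm here) can be reconstructed from a single 2D
exposure — attractive for imaging fast organelle dynamics (mitochondria,
ER) in living cells, where the photon budget rules out scanning.

The package implements the full computational chain on synthetic data:

- **Wave-optics PSF simulation** (`flfm.optics`) — scalar Fresnel
  diffraction through the objective pupil, Fourier lens and the
  diffractive optical element (DOE) that acts as the lenslet array
  (pitch 3.25 mm, f-number ≈ 37, f_ML = 120 mm behind a 100×/1.4 NA
  objective by default).
- **Image formation** (`flfm.forward`) — the measurement model
  `y = H∗x + n + b`: depthwise convolution with the PSF plus
  Poisson/Gaussian noise and constant background, with a fitting routine
  that realizes a requested SNR/SBR.
- **View geometry** (`flfm.geometry`) — calibration of lenslet positions
  and rotation from a reference frame; extraction of the three views.
- **Richardson–Lucy deconvolution** (`flfm.deconv`) — the classical
  multi-view RL baseline with exact adjoint and monotone Poisson
  likelihood.
- **Phantoms and training data** (`flfm.phantoms`) — seeded bead,
  hollow-tube ("outer mitochondrial membrane") and filament-network
  ("ER") volumes, and fully reproducible (noisy views, clean views, HR
  stack) training triplets.
- **F-VCD** (`flfm.fvcd`) — the two-stage deep reconstruction:
  *F-Denoise*, an RCAN-style denoiser with a view-attention gate, and
  *F-Reconstruction*, a dilated-convolution + U-Net view-to-depth
  network, trained with the weighted loss
  `0.2·(α|d|₁ + (1−α)d²₂) + 0.8·(MSE + β·gradient)` after per-net
  pretraining. Implemented in pure NumPy with hand-written
  reverse-mode gradients — fully deterministic on CPU.
- **Evaluation** (`flfm.metrics`) — the log-ratio SNR
  `10·log10(Σ(f−f̄)²/Σ(f̂−f)²)`, SSIM/NRMSE, error maps, and spectral
  resolution estimation from the radially averaged power spectrum.
- **Pipeline + CLI** (`flfm.pipeline`, `flfm` command) — an end-to-end
  seeded demo (phantom → PSF → simulate → calibrate → deconvolve →
  train → infer → evaluate) with a checksummed run manifest.

## Worked example

Simulate the reduced-scale instrument, image three fluorescent beads,
and reconstruct them by Richardson–Lucy:

```python
import numpy as np
from flfm import (CalibrationResult, DeconvConfig, PhantomSpec,
                  compute_psf, desk_scale_config, extract_views,
                  forward_project, localize_peak, make_phantom,
                  richardson_lucy)
from flfm.optics import psf_views

cfg = desk_scale_config()                 # 224 px sensor, 41 z-planes
psf = compute_psf(cfg)
cal = CalibrationResult.from_config(cfg)

voxel = (cfg.depth_step_um * 1e3, cfg.lateral_sampling_nm,
         cfg.lateral_sampling_nm)
beads = make_phantom(PhantomSpec(kind="beads", count=3,
                                 shape=(41, 64, 64), voxel_size_nm=voxel,
                                 bead_diameter_nm=260,
                                 bead_min_separation_nm=3000, seed=0))
lf = forward_project(beads, psf)          # one 2D light-field frame
views = extract_views(lf, cal)            # (3, 84, 84) sub-aperture views
vol = richardson_lucy(views, psf_views(psf, cal),
                      DeconvConfig(iterations=30))
print("energy spread across depth:",
      f"{100 * np.ptp(psf.energy_per_depth()) / psf.energy_per_depth().mean():.2f}%")
print("views:", views.data.shape)
print("reconstructed grid:", vol.data.shape)
print("bead near (29.5, 60.5, 47) localized at:",
      np.round(localize_peak(vol.data, (29.5, 60.5, 47)), 2))
```

Output:

```
energy spread across depth: 1.87%
views: (3, 84, 84)
reconstructed grid: (41, 84, 84)
bead near (29.5, 60.5, 47) localized at: [28.79 60.48 47.02]
```

The PSF conserves energy across the depth range (the DOE is pure phase,
so only sensor-edge clipping loses light), the single 2D frame yields a
41-plane volume, and the bead is localized to well within one voxel
(one voxel = 175 nm axially, 130 nm laterally at this scale).

The same flow is available from the shell:

```bash
flfm psf --out psf.tif
flfm phantom --kind hollow_tubes --seed 3 --out gt.tif
flfm simulate --volume gt.tif --psf psf.tif --snr -1.62 --seed 7 --out lf.tif
flfm deconv --views views.tif --psf psf.tif --cal cal.yaml --out vol.tif
flfm pipeline --out run/           # complete seeded end-to-end demo
```

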