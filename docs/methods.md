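# Methods

This note documents the models, numerical choices and limitations behind
`flfm`. The package simulates a three-view Fourier light-field microscope
(FLFM) end to end and reconstructs volumes from single light-field frames
two ways: classical multi-view Richardson–Lucy (RL) deconvolution, and the
two-stage F-VCD network (view-correlated denoising followed by a
view-to-depth transformation).

## Optical model

The instrument is a high-NA epifluorescence microscope whose objective
pupil is relayed by a Fourier lens (focal length `f_FL`) onto a diffractive
optical element (DOE). The DOE carries the wrapped quadratic phases of
three lenslets (pitch `d`, focal length `f_ML`, f-number `f_ML/d ≈ 37`),
which segment the pupil into three sub-apertures; a camera at the lenslet
focal plane records three perspective views side by side.

The default configuration matches a real instrument of this type: 100×/1.4
NA oil objective (n = 1.518), emission 510 nm (EGFP), `f_FL` = 300 mm,
`d` = 3.25 mm, `f_ML` = 120 mm, 6.5 µm sensor pixels, 41 depth planes over
±3.5 µm. Derived constants: pupil radius at the DOE `R_p = NA·f_FL/M`
(4.2 mm), total magnification `M·f_ML/f_FL` (40×), sensor-referred
sample-space pixel 162.5 nm, z-step 175 nm.

The exact geometry of the lenslet arrangement is not among the
instrument's published constants; we default to an equilateral triple of
mutually tangent apertures inscribed in the pupil (centres at radius
`d/√3`, angles 90°/210°/330°), which maximizes aperture use. It is
overridable in the configuration.

### PSF computation

The PSF is computed per depth plane by scalar Fresnel diffraction:

1. a point emitter at defocus `z` contributes the pupil field
   `exp(i·(2π/λ)·z·sqrt(n² − NA²·s²))` on the uniform pupil disc
   (`s` = normalized pupil radius) — the standard high-NA defocus phase;
2. the field is multiplied by the DOE transmission: binary aperture masks
   times the wrapped thin-lens phase `−π r²/(λ f_ML)` per lenslet;
3. a single-FFT Fresnel propagation over `f_ML` (the propagation chirp
   included analytically) gives the sensor field; its squared modulus is
   the intensity PSF.

Two discretization constraints are enforced. The Fourier-plane extent is
fixed by the sensor pixel pitch (`λ f_ML / Δx`); the FFT grid size is
chosen (or validated) against the Nyquist bound on the combined local
frequency of defocus phase plus lenslet linear phase, and a
`SamplingError` names the first offending depth if violated. Because the
DOE is pure phase inside an energy-preserving mask, total sensor energy
per depth is constant by Parseval up to sensor-edge clipping; the tests
assert <5% variation.

The geometric parallax prediction used as an oracle is the first-moment
identity of the Fourier transform: the intensity centroid of a view equals
`λ f_ML/2π` times the aperture-averaged gradient of the defocus phase. At
NA 1.4 this aperture average differs from the value at the aperture centre
by ~15%, so the prediction integrates over the lenslet disc numerically
(polar quadrature, no FFT). For +z the sub-images move toward the optical
axis.

### Desk-scale preset

All tests and the acceptance studies run a reduced-scale preset
(`desk_scale_config`): a 250× objective image on a 2×-binned sensor
(13 µm pixels), lenslet pitch 1.55 mm, 224² sensor, FFT grid 400. Every
geometric relation of the full-scale system is preserved (the preset is
the same physics, just smaller: views ~64–84 px, parallax ~4.3 px/µm,
130 nm lateral sampling) while a full PSF computes in under a second.
The full-scale default is exercised by configuration tests only.

## Image formation and noise

A clean light field is `y = Σ_z x_z ⊛ H_z`, computed with zero-padded
rFFT convolutions (no circular wrap) whose origin convention places the
optical axis on the FFT-centre pixel `g//2`; a centred single-voxel
impulse reproduces the PSF plane to machine precision.

Corruption follows the physical order shot → read → offset:
`Poisson(gain·clean)/gain + N(0, σ²) + b`, clipped at zero (camera output
after offset subtraction is nonnegative). The expectation before clipping
is `clean + b` and the variance `clean/gain + σ²`; a Monte-Carlo test
checks both.

`fit_noise_to_target` inverts this model for a requested SNR (the
log-ratio definition below) and optionally a signal-to-background ratio
(SBR). SBR is defined as mean(foreground)/mean(background) with the
foreground mask from Otsu's threshold on the clean image; the background
level then has a closed form. The Gaussian σ is found by bisection on the
SNR measured on an actual seeded corruption, which automatically accounts
for the clip bias; the Poisson gain defaults to the value that lets shot
noise carry half the target noise power. Targets above 60 dB are rejected
as beyond the supported noiseless limit.

## View geometry

Conventions are fixed so that crops are bit-exact: 0-based (row, col)
indices, origin top-left, canonical view order by angle from the +x axis
(ties broken by distance from the sensor centre). Calibration estimates
the three sub-aperture centroids of a bright reference frame (connected
components above 10% of max) and the arrangement rotation as the mean
circular offset from the canonical angles modulo the 120° symmetry.
Extraction rotates by −rotation (bilinear, constant-0) *then* crops;
at zero rotation it is a pure integer crop and round trips are exact.

## Richardson–Lucy baseline

The multi-view forward operator applies each view's per-depth kernel bank
(cropped from the full PSF around the calibrated centres) by zero-padded
FFT convolution; its adjoint is exact to machine precision (dot-product
tested), which guarantees the multiplicative update

    x ← x · [Aᵀ(y/(Ax+ε))] / Aᵀ1

does not decrease the Poisson likelihood. Defaults: 30 iterations,
ε = 1e−9 as a ratio guard (keeping the multiplicative structure exact),
flat initialization. Beads are localized in reconstructions with 3-point
parabolic peak interpolation (sub-voxel, insensitive to the asymmetric
convergence tails RL exhibits at early iterations); at the default 30
iterations well-separated beads localize to ≲1 voxel on the 175 nm z-grid
and the residual axial bias (toward focus) decays to <0.5 voxel by ~80
iterations.

## Phantoms

Three seeded families emulate the study's specimens at confocal-like
voxel sizes: `beads` (spheres, optional minimum-separation rejection
sampling — the standard sparse localization target), `hollow_tubes`
(persistent random-walk axes rasterized and shelled via a Euclidean
distance transform; outer diameter 400–1000 nm, wall 80–150 nm, lumen at
15% of wall intensity, so walls are unresolvable in single
diffraction-limited views but resolvable at the reconstruction scale) and
`filament_network` (thin persistent curves). Volumes are trilinearly
resampled onto the 41-plane FLFM grid with exact flux renormalization.

Training triplets are produced by the actual instrument model: resample →
project → extract views → corrupt at a target SNR drawn uniformly from
the configured range (noise fitted against the view region, since the
raw sensor frame is mostly dark). Optional flip/rot90 augmentation is
applied identically to all members of a triplet and flagged `augmented`,
because image-space flips do not commute with the three-view parallax
geometry; augmented triplets are excluded from physics-consistency tests.

## F-VCD

Both sub-nets are implemented as a small NumPy layer stack with explicit
reverse-mode gradients (convolution via im2col, instance norm, leaky
rectifiers, squeeze-excite gates, sub-pixel shuffle, Adam), every backward
pass pinned by finite-difference tests. This keeps training bit-exactly
reproducible on CPU under a fixed seed.

**F-Denoise** is an RCAN-style global-residual trunk over the three views
with channel attention inside each residual block, plus a *view-attention*
input gate: a squeeze-excite over the view axis producing one sigmoid
weight per view (the view axis takes the place of the channel axis in the
gate — the dimension-permutation formulation of view attention).
Disabling the branch yields a plain RCAN with exactly the gate parameters
removed (structural test).

**F-Reconstruction** expands the three views through three dilated
convolution blocks (rates 1/2/4, widths growing 3→12→16→24 by default) and
maps features to the 41 depth planes through a two-level U-Net with
residual encoder blocks, instance normalization and LeakyReLU; lateral
upscaling, when configured, uses pixel shuffle. The output layer is linear
with clamping at zero applied only at inference, so weak signals are not
truncated during optimization.

**Losses.** Denoise: `α·mean|d| + (1−α)·mean d²` with α = 0.5.
Reconstruction: MSE plus `β` (default 0.1) times the average over the
(z, y, x) axes of the mean squared difference of forward finite
differences. Joint: `0.2·denoise + 0.8·reconstruction`. Training follows
pretrain-then-joint with Adam and per-epoch exponential learning-rate
decay; default patch sizes are 160×160×3 for denoiser pretraining and
80×80×3 for joint optimization (larger pretraining patches help the
denoiser; at desk scale the patches clip to the view size). Validation
loss is evaluated each epoch on full frames and the best epoch's
parameters are restored.

**Tiled inference** uses margin-discard tiles whose origins share the
whole image's stride-4 phase; for purely convolutional sub-nets the
stitched result equals whole-image inference exactly once the margin
covers the receptive field. Global-pooling gates and instance norm see
per-tile statistics, making tiling approximate for such models — the
exactness test therefore uses a gate-free, norm-free configuration.

## Evaluation

SNR is the log-ratio definition
`10·log10(Σ(f−f̄)² / Σ(f̂−f)²)` with `f̄` the mean of the reference over
the grid; a constant reference raises, zero noise returns +∞. SSIM is the
standard windowed form (uniform 7-window, K1 = 0.01, K2 = 0.03, sample
covariance) via scikit-image and NRMSE is RMSE over the reference dynamic
range — both computed after min-max normalization of both images by the
*reference's* range, which changes values and is therefore fixed here.
Error maps are |gt − pred| under the same normalization.

Spectral resolution: radially averaged power spectrum; noise floor = mean
power over the top decile of frequencies; cutoff = first frequency where
the lightly smoothed spectrum falls to floor + 0.5% of the floor-to-peak
excursion; resolution = pixel/cutoff. Degenerate spectra (no power above
3× floor, or no crossing below Nyquist) return the two-pixel sampling
limit with a flag. The criterion is isolated behind one function so a
decorrelation-based estimator could be swapped in.

## Desk-scale learning study

The reference study (`flfm.pipeline.hollow_tube_study`, also run by
`scripts/acceptance.py`) trains on 32 hollow-tube triplets at view size
64², SNRs drawn from −2…+6 dB (the regime of the real experiments reaches
−1.62 dB), with reduced widths, and evaluates on held-out triplets:
denoised-view SNR gain over the inputs, and 3D SSIM of the F-VCD volume
vs the RL volume computed from the same noisy views. Problem sizes and
epoch counts are the package's own desk-scale choices; they are far below
the real study's training scale, so the study demonstrates the ordering
and mechanisms (denoising gain, learned view-to-depth transformation
competitive with deconvolution), not full-scale resolution figures.

## Known limitations

- Scalar diffraction with a uniform pupil: no apodization, vectorial
  effects or aberrations; the DOE is modelled as its ideal equivalent
  lenslet phase.
- Noise is spatially i.i.d.; no fixed-pattern noise, EM gain or
  spatially varying background.
- Phantoms are geometric; they do not reproduce the texture, crowding or
  motion of real organelles, so passing tests bound correctness of the
  pipeline, not biological image quality.
- The NumPy networks are desk-scale (tens of thousands of parameters);
  results quantify relative behaviour under the simulated study
  conditions only.
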