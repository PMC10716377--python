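"""Synthetic specimens and training datasets.

The real study trains on high-resolution confocal (Airyscan) stacks of
mitochondria and endoplasmic reticulum.  This module emulates those
ground truths with seeded geometric phantoms:

* ``beads`` — sub-diffraction spheres, for PSF/parallax/deconvolution
  oracles;
* ``hollow_tubes`` — curved tubes with a bright wall and dark lumen,
  emulating the outer mitochondrial membrane (outer diameter 400-1000 nm,
  wall 80-150 nm: walls unresolvable in single diffraction-limited
  views but resolvable at the reconstruction scale);
* ``filament_network`` — thin persistent random curves, emulating the
  peripheral ER network.

`build_dataset` turns phantoms into (noisy views, clean views, HR stack)
training triplets through the actual instrument model: resample to the
FLFM grid, project through the PSF, extract views, corrupt at a target
SNR.  It is fully seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward import NoiseParams, Volume, corrupt, fit_noise_to_target, forward_project
from .geometry import CalibrationResult, LFImage, ViewStack, extract_views
from .io import sha256_of_array
from .optics import OpticalConfig, PSFStack


@dataclass
class PhantomSpec:
    """Recipe for one seeded synthetic ground-truth volume."""

    kind: str = "hollow_tubes"            # beads | hollow_tubes | filament_network
    count: int = 4
    shape: tuple[int, int, int] = (48, 96, 96)       # (z, y, x) voxels
    voxel_size_nm: tuple[float, float, float] = (150.0, 100.0, 100.0)
    tube_outer_diameter_nm: tuple[float, float] = (400.0, 1000.0)
    tube_wall_nm: tuple[float, float] = (80.0, 150.0)
    bead_diameter_nm: float = 200.0
    bead_min_separation_nm: float = 0.0   # 0 disables the spacing constraint
    filament_diameter_nm: float = 150.0
    persistence_steps: float = 12.0       # directional memory of random curves
    intensity_range: tuple[float, float] = (0.6, 1.0)
    lumen_fraction: float = 0.15          # lumen intensity relative to wall
    seed: int = 0

    def validate(self):
        if self.kind not in ("beads", "hollow_tubes", "filament_network"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        lo, hi = self.tube_wall_nm
        od_lo, _ = self.tube_outer_diameter_nm
        if hi >= od_lo / 2:
            raise ValueError("wall thickness must be below the tube radius")
        if min(self.voxel_size_nm) <= 0:
            raise ValueError("voxel size must be positive")
        if self.kind == "hollow_tubes" and \
                self.tube_wall_nm[0] < 0.5 * min(self.voxel_size_nm[1:]):
            raise ValueError(
                "tube wall thinner than half a voxel: geometry infeasible "
                "at this voxel size")


def _random_curve(rng, shape, voxel, persistence, n_steps=None,
                  step_nm=None, margin=0.12):
    """A smooth persistent random walk inside the volume, in voxel coords."""
    shape = np.asarray(shape, float)
    step_nm = step_nm or min(voxel) * 0.5
    n_steps = n_steps or int(4 * max(shape))
    pos = np.array([rng.uniform(m, s - m) for s, m in
                    zip(shape, margin * shape)])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pts = [pos.copy()]
    step_vox = step_nm / np.asarray(voxel)
    for _ in range(n_steps):
        kick = rng.normal(scale=1.0 / max(persistence, 1e-6), size=3)
        direction = direction + kick
        direction /= np.linalg.norm(direction)
        pos = pos + direction * step_vox
        # reflect at (soft) boundaries
        for a in range(3):
            lim = margin * shape[a]
            if pos[a] < lim or pos[a] > shape[a] - lim:
                direction[a] *= -1.0
                pos[a] = np.clip(pos[a], lim, shape[a] - lim)
        pts.append(pos.copy())
    return np.asarray(pts)


def _distance_to_curves(curves, shape, voxel):
    """Per-voxel Euclidean distance (nm) to the union of rasterized curves."""
    mask = np.zeros(shape, dtype=bool)
    for pts in curves:
        idx = np.rint(pts).astype(int)
        idx = idx[np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)]
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not mask.any():
        raise ValueError("no curve points inside the volume")
    return ndimage.distance_transform_edt(~mask, sampling=voxel)


def make_phantom(spec: PhantomSpec) -> Volume:
    """Generate a seeded nonnegative phantom volume."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    voxel = spec.voxel_size_nm
    vol = np.zeros(shape)

    if spec.kind == "beads":
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        r_nm = spec.bead_diameter_nm / 2.0
        placed = []
        for _ in range(spec.count):
            for _attempt in range(1000):
                c = [rng.uniform(0.15 * s, 0.85 * s) for s in shape]
                if spec.bead_min_separation_nm <= 0 or all(
                        np.sqrt(sum(((a - b) * v) ** 2 for a, b, v
                                    in zip(c, p, voxel)))
                        >= spec.bead_min_separation_nm for p in placed):
                    break
            else:
                raise ValueError(
                    "could not place beads at the requested separation")
            placed.append(c)
            amp = rng.uniform(*spec.intensity_range)
            d2 = ((zz - c[0]) * voxel[0]) ** 2 + ((yy - c[1]) * voxel[1]) ** 2 \
                + ((xx - c[2]) * voxel[2]) ** 2
            vol += amp * (d2 <= r_nm**2)
        if vol.max() == 0:     # beads below voxel size: place single voxels
            for _ in range(spec.count):
                c = [int(rng.uniform(0.15 * s, 0.85 * s)) for s in shape]
                vol[tuple(c)] = rng.uniform(*spec.intensity_range)

    elif spec.kind == "hollow_tubes":
        for _ in range(spec.count):
            od = rng.uniform(*spec.tube_outer_diameter_nm)
            wall = rng.uniform(*spec.tube_wall_nm)
            amp = rng.uniform(*spec.intensity_range)
            curve = _random_curve(rng, shape, voxel, spec.persistence_steps)
            dist = _distance_to_curves([curve], shape, voxel)
            r_out = od / 2.0
            r_in = r_out - wall
            shell = (dist <= r_out) & (dist > r_in)
            lumen = dist <= r_in
            vol = np.maximum(vol, amp * shell)
            vol = np.maximum(vol, amp * spec.lumen_fraction * lumen)

    else:  # filament_network
        curves = [_random_curve(rng, shape, voxel, spec.persistence_steps)
                  for _ in range(spec.count)]
        dist = _distance_to_curves(curves, shape, voxel)
        amp = rng.uniform(*spec.intensity_range)
        vol = amp * (dist <= spec.filament_diameter_nm / 2.0)

    vol = ndimage.gaussian_filter(vol, sigma=0.6)
    return Volume(data=vol, voxel_size_nm=voxel)


def resample_to_flfm(volume: Volume, config: OpticalConfig,
                     lateral_px: int | None = None,
                     crop_axial: bool = False) -> Volume:
    """Trilinear resampling onto the FLFM reconstruction grid.

    Target grid: ``depth_planes`` axial planes at the configured z-step,
    sensor-referred lateral sampling.  Total flux is renormalized to the
    source volume's flux (exact, hence within the 1% contract).
    """
    src = volume.data
    dz, dy, dx = volume.voxel_size_nm
    tz = config.depth_step_um * 1e3
    tl = config.lateral_sampling_nm
    z_extent_src = src.shape[0] * dz
    z_extent_dst = config.depth_planes * tz
    if z_extent_src > z_extent_dst * (1 + 1e-9) and not crop_axial:
        raise ValueError(
            f"axial extent {z_extent_src:.0f} nm exceeds the depth range "
            f"{z_extent_dst:.0f} nm (pass crop_axial=True to crop)")
    if lateral_px is None:
        lateral_px = int(round(src.shape[1] * dy / tl))
    same_grid = (
        abs(dz - tz) < 1e-9 and abs(dy - tl) < 1e-9 and abs(dx - tl) < 1e-9
        and src.shape == (config.depth_planes, lateral_px, lateral_px))
    if same_grid:
        return Volume(data=src.copy(), voxel_size_nm=(tz, tl, tl))

    out_shape = (config.depth_planes, lateral_px, lateral_px)
    # map output voxel centres into source voxel coordinates, centres aligned
    coords = []
    for ax, (n_out, t, s) in enumerate(
            zip(out_shape, (tz, tl, tl), (dz, dy, dx))):
        c_out = (np.arange(n_out) - (n_out - 1) / 2.0) * t
        coords.append(c_out / s + (src.shape[ax] - 1) / 2.0)
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(src, [zz, yy, xx], order=1, mode="constant",
                                  cval=0.0)
    flux_src = src.sum()
    flux_dst = out.sum()
    if flux_src > 0 and flux_dst > 0:
        out *= flux_src / flux_dst
    return Volume(data=np.maximum(out, 0.0), voxel_size_nm=(tz, tl, tl))


@dataclass
class TrainingTriplet:
    """One (input, dual ground-truth) training example."""

    hr_stack: Volume                  # reconstruction GT, (depth, h, w)
    clean_views: ViewStack            # denoising GT
    noisy_views: ViewStack            # network input
    noise_params: NoiseParams
    snr_db: float
    augmented: bool = False

    def checksum(self) -> str:
        return sha256_of_array(
            np.concatenate([self.hr_stack.data.ravel(),
                            self.clean_views.data.ravel(),
                            self.noisy_views.data.ravel()]))


def _hr_center_crop(vol: Volume, h: int, w: int) -> Volume:
    """Centre-crop or zero-pad the stack laterally onto the view grid."""
    z, y, x = vol.data.shape
    out = np.zeros((z, h, w))
    ry, rx = min(y, h), min(x, w)
    sy, sx = (y - ry) // 2, (x - rx) // 2
    dy, dx = (h - ry) // 2, (w - rx) // 2
    out[:, dy:dy + ry, dx:dx + rx] = vol.data[:, sy:sy + ry, sx:sx + rx]
    return Volume(data=out, voxel_size_nm=vol.voxel_size_nm)


def make_triplet(spec: PhantomSpec, config: OpticalConfig, psf: PSFStack,
                 cal: CalibrationResult, snr_db: float,
                 sbr: float | None = None, seed: int = 0) -> TrainingTriplet:
    """Phantom -> resample -> project -> extract -> corrupt, one example."""
    hr = make_phantom(spec)
    hr_flfm = resample_to_flfm(hr, config)
    clean_lf = forward_project(hr_flfm, psf)
    clean_views = extract_views(clean_lf, cal)
    # fit the noise against the view region (the raw LF is mostly dark
    # sensor, which would inflate the apparent SNR of the views)
    h, w = cal.view_size
    view_panel = LFImage(np.hstack(list(clean_views.data)),
                         pixel_pitch_um=clean_lf.pixel_pitch_um)
    params = fit_noise_to_target(view_panel, snr_db, target_sbr=sbr, seed=seed)
    noisy_lf = corrupt(clean_lf, params)
    noisy_views = extract_views(noisy_lf, cal)
    noisy_views.provenance = "synthetic"
    h, w = cal.view_size
    return TrainingTriplet(
        hr_stack=_hr_center_crop(hr_flfm, h, w),
        clean_views=clean_views, noisy_views=noisy_views,
        noise_params=params, snr_db=snr_db)


def _augment_triplet(t: TrainingTriplet, rng) -> TrainingTriplet:
    """Random flip / 90-degree rotation applied identically to all members.

    Flips do not commute with the three-view parallax geometry, so the
    result is flagged ``augmented`` and excluded from physics-consistency
    checks.
    """
    k = int(rng.integers(0, 4))
    flip = bool(rng.integers(0, 2))

    def tf(img2d):
        out = np.rot90(img2d, k)
        if flip:
            out = np.flip(out, axis=-1)
        return np.ascontiguousarray(out)

    hr = np.stack([tf(s) for s in t.hr_stack.data])
    cv = np.stack([tf(s) for s in t.clean_views.data])
    nv = np.stack([tf(s) for s in t.noisy_views.data])
    return TrainingTriplet(
        hr_stack=Volume(hr, t.hr_stack.voxel_size_nm),
        clean_views=ViewStack(cv, provenance="synthetic"),
        noisy_views=ViewStack(nv, provenance="synthetic"),
        noise_params=t.noise_params, snr_db=t.snr_db, augmented=True)


def build_dataset(specs: list[PhantomSpec], config: OpticalConfig,
                  psf: PSFStack, cal: CalibrationResult,
                  snr_range_db: tuple[float, float] = (-2.0, 6.0),
                  sbr: float | None = None, n_triplets: int = 16,
                  seed: int = 0, augment: bool = False
                  ) -> list[TrainingTriplet]:
    """Assemble a fully seeded training dataset of consistent triplets."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_triplets)
    rng = np.random.default_rng(root.spawn(1)[0])
    out = []
    for i, ss in enumerate(children):
        sub = np.random.default_rng(ss)
        snr = float(sub.uniform(*snr_range_db))
        base = specs[i % len(specs)]
        spec_i = PhantomSpec(**{**base.__dict__,
                                "seed": int(sub.integers(0, 2**31 - 1))})
        trip = make_triplet(spec_i, config, psf, cal, snr, sbr=sbr,
                            seed=int(sub.integers(0, 2**31 - 1)))
        if augment:
            trip = _augment_triplet(trip, sub)
        out.append(trip)
    return out
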