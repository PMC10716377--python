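"""Wave-optics model of a Fourier light-field microscope (FLFM).

The instrument: a high-NA objective, a Fourier lens that relays the
objective pupil onto a diffractive optical element (DOE), and a camera at
the DOE's back focal plane.  The DOE carries the wrapped quadratic phases
of three lenslets which segment the Fourier pupil into three perspective
views, so a single camera exposure records three sub-images of the sample
whose mutual parallax encodes depth.

The point-spread function is computed by scalar Fresnel diffraction:

1. the field of a point emitter at defocus ``z`` is represented in the
   pupil (Fourier) plane as a uniform disc carrying the high-NA defocus
   phase ``(2*pi/lambda) * z * sqrt(n^2 - NA^2 * s^2)`` with ``s`` the
   normalized pupil radius;
2. the field is multiplied by the DOE transmission (aperture masks and
   wrapped thin-lens phases of focal length ``f_ML``);
3. a single-FFT Fresnel propagation over ``f_ML`` yields the sensor
   field; its squared modulus is the intensity PSF for that depth.

Because the lenslet apertures are pure phase inside an energy-preserving
mask, total sensor energy per depth is constant up to sensor-edge
clipping (Parseval), which the tests rely on.

Geometric relations used throughout the package:

* pupil radius at the DOE plane:  ``R_p = NA * f_FL / M``;
* total magnification sample -> sensor:  ``M_tot = M * f_ML / f_FL``;
* sensor-referred sample-space pixel:  ``pixel_pitch / M_tot``;
* each view's sub-image is centred at the lenslet centre (in sensor
  millimetres), and the parallax slope of view *j* is

  ``dx/dz = f_ML * NA^2 * s_j / (R_p * sqrt(n^2 - NA^2 * s_j^2))``

  directed along the lenslet-centre direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import fft as sfft

from .io import write_tiff, write_yaml


class ConfigurationError(ValueError):
    """Raised when an OpticalConfig violates a physical constraint."""


class SamplingError(ValueError):
    """Raised when the FFT grid undersamples the pupil phase."""


def _default_lenslet_centers(pitch_mm: float, count: int = 3) -> np.ndarray:
    """Equilateral arrangement of mutually tangent lenslets.

    Centres sit at radius ``pitch / sqrt(3)`` at angles 90, 210, 330
    degrees from the +x axis, so the three apertures touch pairwise and
    inscribe the Fourier pupil as tightly as the pitch allows.
    """
    if count != 3:
        raise ConfigurationError("only the three-lenslet arrangement is supported")
    radius = pitch_mm / np.sqrt(3.0)
    angles = np.deg2rad([90.0, 210.0, 330.0])
    return np.stack([radius * np.cos(angles), radius * np.sin(angles)], axis=1)


@dataclass
class OpticalConfig:
    """All optical/system constants of the FLFM instrument.

    Units are stated per field; derived quantities are exposed as
    properties in SI units.
    """

    objective_magnification: float = 100.0
    numerical_aperture: float = 1.4
    immersion_index: float = 1.518
    emission_wavelength_nm: float = 510.0
    fourier_lens_focal_mm: float = 300.0
    lenslet_pitch_mm: float = 3.25
    lenslet_focal_mm: float = 120.0
    f_number: float | None = None            # defaults to f_ML / pitch (~36.9)
    lenslet_count: int = 3
    lenslet_centers_mm: np.ndarray | None = None
    sensor_pixel_pitch_um: float = 6.5
    sensor_grid: tuple[int, int] = (1024, 1024)
    depth_planes: int = 41
    depth_half_range_um: float = 3.5         # grid spans +- this, ~7 um total
    iris_diameter_at_nip_mm: float | None = None
    fft_grid: int | None = None              # None -> auto from band limit

    def __post_init__(self):
        if self.lenslet_centers_mm is None:
            self.lenslet_centers_mm = _default_lenslet_centers(
                self.lenslet_pitch_mm, self.lenslet_count)
        self.lenslet_centers_mm = np.asarray(self.lenslet_centers_mm, dtype=float)
        if self.f_number is None:
            self.f_number = self.lenslet_focal_mm / self.lenslet_pitch_mm
        self.validate()

    # ---- derived quantities (SI) -------------------------------------
    @property
    def wavelength_m(self) -> float:
        return self.emission_wavelength_nm * 1e-9

    @property
    def pupil_radius_m(self) -> float:
        """Radius of the objective-pupil image at the DOE plane."""
        return (self.numerical_aperture * self.fourier_lens_focal_mm * 1e-3
                / self.objective_magnification)

    @property
    def total_magnification(self) -> float:
        return (self.objective_magnification
                * self.lenslet_focal_mm / self.fourier_lens_focal_mm)

    @property
    def lateral_sampling_nm(self) -> float:
        """Sample-space size of one sensor pixel."""
        return self.sensor_pixel_pitch_um * 1e3 / self.total_magnification

    @property
    def depth_step_um(self) -> float:
        return 2.0 * self.depth_half_range_um / (self.depth_planes - 1)

    @property
    def depth_values_um(self) -> np.ndarray:
        return np.linspace(-self.depth_half_range_um, self.depth_half_range_um,
                           self.depth_planes)

    @property
    def pupil_plane_extent_m(self) -> float:
        """Fourier-plane field of view implied by the sensor pixel pitch."""
        return (self.wavelength_m * self.lenslet_focal_mm * 1e-3
                / (self.sensor_pixel_pitch_um * 1e-6))

    @property
    def view_centers_px(self) -> np.ndarray:
        """Geometric sub-image centres on the sensor, (view, [row, col]).

        Lenslet (x, y) maps to (row, col) with x -> +col and y -> -row
        (image rows increase downwards).  The optical axis sits on the
        FFT-centre pixel ``grid // 2``.
        """
        px = self.sensor_pixel_pitch_um * 1e-3          # mm
        cy = self.sensor_grid[0] // 2
        cx = self.sensor_grid[1] // 2
        rows = cy - self.lenslet_centers_mm[:, 1] / px
        cols = cx + self.lenslet_centers_mm[:, 0] / px
        return np.stack([rows, cols], axis=1)

    def parallax_slope_px_per_um(self) -> np.ndarray:
        """Predicted d(centroid)/dz per view, px/um, (view, [row, col]).

        The intensity centroid of a view equals the aperture-averaged
        gradient of the defocus phase times lambda*f/(2*pi) (first-moment
        identity of the Fourier transform with uniform aperture
        amplitude), so the slope is the average over the lenslet disc of

            -f_ML * NA^2 * u / (R_p^2 * sqrt(n^2 - NA^2 |u|^2 / R_p^2))

        For +z the sub-image moves toward the optical axis.
        """
        n = self.immersion_index
        na = self.numerical_aperture
        rp = self.pupil_radius_m
        f_ml = self.lenslet_focal_mm * 1e-3
        r_ap = self.lenslet_pitch_mm * 1e-3 / 2.0
        # polar quadrature over the lenslet disc
        rho = (np.arange(64) + 0.5) / 64 * r_ap
        tht = np.arange(128) / 128 * 2 * np.pi
        RR, TT = np.meshgrid(rho, tht, indexing="ij")
        out = []
        for cx, cy in self.lenslet_centers_mm * 1e-3:
            ux = cx + RR * np.cos(TT)
            uy = cy + RR * np.sin(TT)
            s2 = (ux**2 + uy**2) / rp**2
            denom = np.sqrt(np.maximum(n**2 - na**2 * s2, 1e-12))
            gx = -f_ml * na**2 * ux / (rp**2 * denom)
            gy = -f_ml * na**2 * uy / (rp**2 * denom)
            w = RR                                # area element
            vx = np.sum(gx * w) / np.sum(w)       # m shift per m z
            vy = np.sum(gy * w) / np.sum(w)
            # m/m == um/um; (x, y) -> (row, col) with row = -y
            out.append(np.array([-vy, vx]) / self.sensor_pixel_pitch_um)
        return np.asarray(out)

    # ---- validation ---------------------------------------------------
    def validate(self) -> None:
        if not self.numerical_aperture < self.immersion_index:
            raise ConfigurationError(
                "numerical aperture must be below the immersion index")
        fno = self.lenslet_focal_mm / self.lenslet_pitch_mm
        if abs(fno - self.f_number) > 0.01 * self.f_number:
            raise ConfigurationError(
                f"lenslet f-number inconsistent: f_ML/d = {fno:.2f} "
                f"vs configured {self.f_number:.2f}")
        if self.depth_planes % 2 != 1:
            raise ConfigurationError("depth_planes must be odd (z = 0 plane)")
        centers = self.lenslet_centers_mm
        if len(centers) != self.lenslet_count:
            raise ConfigurationError("lenslet_centers length != lenslet_count")
        r_ap = self.lenslet_pitch_mm / 2.0
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(*(centers[i] - centers[j]))
                if d < 2 * r_ap - 1e-9:
                    raise ConfigurationError(
                        f"lenslet apertures {i} and {j} overlap "
                        f"(centre distance {d:.3f} mm < pitch)")
        pupil_r_mm = self.pupil_radius_m * 1e3
        for i, c in enumerate(centers):
            if np.hypot(*c) + r_ap > pupil_r_mm * (1 + 1e-9):
                raise ConfigurationError(
                    f"lenslet {i} aperture extends outside the Fourier pupil "
                    f"({np.hypot(*c) + r_ap:.3f} mm > {pupil_r_mm:.3f} mm)")
        if np.max(np.abs(centers)) * 2 + self.lenslet_pitch_mm \
                > self.pupil_plane_extent_m * 1e3:
            raise ConfigurationError(
                "Fourier-plane extent implied by the sensor pixel pitch is "
                "too small to hold the lenslet apertures")

    # ---- serialization -----------------------------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["lenslet_centers_mm"] = np.asarray(d["lenslet_centers_mm"]).tolist()
        d["sensor_grid"] = list(self.sensor_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        d = dict(d)
        if d.get("lenslet_centers_mm") is not None:
            d["lenslet_centers_mm"] = np.asarray(d["lenslet_centers_mm"])
        if "sensor_grid" in d:
            d["sensor_grid"] = tuple(d["sensor_grid"])
        return cls(**d)

    def scaled_copy(self, **kw) -> "OpticalConfig":
        return replace(self, **kw)


def desk_scale_config(**overrides) -> OpticalConfig:
    """A physically self-consistent reduced-scale instrument.

    Same optical train as the default, but a 250x objective image with a
    2x-binned sensor (13 um pixels) and a 1.55 mm-pitch lenslet triple,
    which shrinks the three sub-images onto a 224 px sensor so that a
    full simulate/reconstruct cycle runs in seconds.  View windows are
    ~64 px with ~4.3 px/um of parallax, preserving every geometric
    property of the full-scale system.
    """
    kw = dict(
        objective_magnification=250.0,
        lenslet_pitch_mm=1.55,
        f_number=120.0 / 1.55,
        sensor_pixel_pitch_um=13.0,
        sensor_grid=(224, 224),
        fft_grid=400,
    )
    kw.update(overrides)
    return OpticalConfig(**kw)


# ---------------------------------------------------------------------------
# Fourier-plane grids and DOE phase
# ---------------------------------------------------------------------------

def _fourier_grid(config: OpticalConfig, n: int):
    """Centred (v, u) coordinate grids in metres, n x n samples.

    u runs along sensor columns, v along sensor rows (y down), so FFT
    output indices align with (row, col) with no sign flips.
    """
    du = config.pupil_plane_extent_m / n
    idx = (np.arange(n) - n // 2) * du
    V, U = np.meshgrid(idx, idx, indexing="ij")
    return V, U, du


def _lenslet_masks(config: OpticalConfig, V, U):
    masks = []
    r_ap = config.lenslet_pitch_mm * 1e-3 / 2.0
    for cx, cy in config.lenslet_centers_mm * 1e-3:
        # y (up) -> -v (row down)
        masks.append((U - cx) ** 2 + (V + cy) ** 2 <= r_ap**2)
    return masks


def doe_phase(config: OpticalConfig, n: int | None = None) -> np.ndarray:
    """Fourier-plane DOE phase map in radians, wrapped to [0, 2*pi).

    Inside each lenslet aperture the phase is the thin-lens quadratic
    ``-pi r^2 / (lambda f_ML)`` about that lenslet's centre; outside all
    apertures the value is 0 (opacity there is handled by the amplitude
    mask, not the phase).
    """
    n = n or _auto_fft_grid(config)
    V, U, _ = _fourier_grid(config, n)
    lam_f = config.wavelength_m * config.lenslet_focal_mm * 1e-3
    phase = np.zeros((n, n))
    masks = _lenslet_masks(config, V, U)
    for mask, (cx, cy) in zip(masks, config.lenslet_centers_mm * 1e-3):
        r2 = (U - cx) ** 2 + (V + cy) ** 2
        phase[mask] = np.mod(-np.pi * r2[mask] / lam_f, 2 * np.pi)
    return phase


def _auto_fft_grid(config: OpticalConfig) -> int:
    """Smallest fast FFT length satisfying the pupil-phase band limit."""
    n_min = max(config.sensor_grid)
    du_max = _max_sampling_interval(config)
    n_req = int(np.ceil(config.pupil_plane_extent_m / du_max))
    return sfft.next_fast_len(max(n_min, n_req))

def _max_sampling_interval(config: OpticalConfig) -> float:
    """Largest pupil-plane sample spacing with no phase aliasing.

    Bounds the combined local spatial frequency of the defocus phase at
    the pupil edge (worst depth) plus the lenslet linear-phase term.
    """
    lam = config.wavelength_m
    n = config.immersion_index
    na = config.numerical_aperture
    zmax = config.depth_half_range_um * 1e-6
    g_defocus = (2 * np.pi / lam) * zmax * na**2 / (
        np.sqrt(n**2 - na**2) * config.pupil_radius_m)
    r_far = (np.max(np.hypot(*(config.lenslet_centers_mm.T))) * 1e-3
             + config.lenslet_pitch_mm * 1e-3 / 2)
    g_lens = 2 * np.pi * r_far / (lam * config.lenslet_focal_mm * 1e-3)
    return np.pi / (g_defocus + g_lens)


def _check_sampling(config: OpticalConfig, n: int) -> None:
    du = config.pupil_plane_extent_m / n
    du_max = _max_sampling_interval(config)
    if du > du_max * (1 + 1e-9):
        # report the shallowest offending depth
        frac = du_max / du
        z_bad = config.depth_half_range_um * frac
        raise SamplingError(
            f"FFT grid {n} undersamples the pupil phase for |z| > "
            f"{z_bad:.2f} um (worst at z = +-{config.depth_half_range_um} um); "
            f"need at least {int(np.ceil(config.pupil_plane_extent_m / du_max))} "
            f"samples")


# ---------------------------------------------------------------------------
# PSF computation
# ---------------------------------------------------------------------------

@dataclass
class PSFStack:
    """The measurement operator H sampled on the sensor grid.

    ``full`` is the assembled (depth, Y, X) intensity PSF of the whole
    sensor; per-view kernel banks are produced by :func:`psf_views`.
    Normalized so the z = 0 plane sums to 1.
    """

    full: np.ndarray                      # (depth, Y, X), float
    depth_values_um: np.ndarray
    pixel_pitch_um: float
    config: OpticalConfig = field(repr=False, default=None)

    def __post_init__(self):
        if np.any(self.full < 0):
            raise ValueError("PSF intensities must be nonnegative")

    @property
    def n_depths(self) -> int:
        return self.full.shape[0]

    def energy_per_depth(self) -> np.ndarray:
        return self.full.sum(axis=(1, 2))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        write_tiff(path, self.full)
        meta = {
            "depth_values_um": self.depth_values_um.tolist(),
            "pixel_pitch_um": float(self.pixel_pitch_um),
            "lenslet_centers_mm": self.config.lenslet_centers_mm.tolist()
            if self.config is not None else None,
            "config": self.config.to_dict() if self.config is not None else None,
        }
        write_yaml(path.with_suffix(".yaml"), meta)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PSFStack":
        from .io import read_tiff, read_yaml
        path = Path(path)
        data = read_tiff(path)
        meta = read_yaml(path.with_suffix(".yaml"))
        cfg = (OpticalConfig.from_dict(meta["config"])
               if meta.get("config") else None)
        return cls(full=data, depth_values_um=np.asarray(meta["depth_values_um"]),
                   pixel_pitch_um=meta["pixel_pitch_um"], config=cfg)


def compute_psf(config: OpticalConfig) -> PSFStack:
    """Simulate the FLFM PSF for every depth plane by Fresnel diffraction."""
    n = config.fft_grid or _auto_fft_grid(config)
    _check_sampling(config, n)
    V, U, du = _fourier_grid(config, n)
    lam = config.wavelength_m
    f_ml = config.lenslet_focal_mm * 1e-3
    rp = config.pupil_radius_m
    na = config.numerical_aperture
    nm = config.immersion_index

    s2 = (U**2 + V**2) / rp**2
    pupil = s2 <= 1.0
    masks = _lenslet_masks(config, V, U)
    aperture = np.zeros((n, n), dtype=bool)
    for m in masks:
        aperture |= m
    aperture &= pupil

    # DOE lens phase + the internal Fresnel chirp of the f_ML propagation.
    phase_static = doe_phase(config, n) + np.pi * (U**2 + V**2) / (lam * f_ml)
    t_static = np.where(aperture, np.exp(1j * phase_static), 0.0)

    # high-NA defocus: axial wavenumber in the immersion medium
    kz = (2 * np.pi / lam) * np.sqrt(
        np.maximum(nm**2 - na**2 * np.clip(s2, 0, 1), 0.0))

    gh, gw = config.sensor_grid
    r0, c0 = (n - gh) // 2, (n - gw) // 2
    out = np.empty((config.depth_planes, gh, gw), dtype=np.float64)
    for i, z_um in enumerate(config.depth_values_um):
        field_p = t_static * np.exp(1j * kz * z_um * 1e-6)
        field_s = sfft.fftshift(sfft.fft2(sfft.ifftshift(field_p)))
        intensity = np.abs(field_s) ** 2
        out[i] = intensity[r0:r0 + gh, c0:c0 + gw]

    i0 = config.depth_planes // 2
    norm = out[i0].sum()
    if norm <= 0:
        raise RuntimeError("degenerate PSF: zero energy at z = 0")
    out /= norm
    return PSFStack(full=out, depth_values_um=config.depth_values_um.copy(),
                    pixel_pitch_um=config.sensor_pixel_pitch_um, config=config)


def psf_views(psf: PSFStack, geometry) -> np.ndarray:
    """Crop the full-sensor PSF into centre-aligned per-view kernels.

    ``geometry`` is a :class:`flfm.geometry.CalibrationResult` sharing
    the PSF's pixel pitch.  Returns a (depth, view, h, w) kernel bank;
    assembling the kernels back at the view centres reproduces the full
    PSF inside the crop windows.
    """
    h, w = geometry.view_size
    gh, gw = psf.full.shape[1:]
    kernels = np.empty((psf.n_depths, len(geometry.view_centers), h, w))
    for v, (r, c) in enumerate(np.rint(geometry.view_centers).astype(int)):
        r0, c0 = r - h // 2, c - w // 2
        if r0 < 0 or c0 < 0 or r0 + h > gh or c0 + w > gw:
            raise ValueError(
                f"view {v} crop window [{r0}:{r0 + h}, {c0}:{c0 + w}] "
                f"exceeds sensor ({gh}, {gw})")
        kernels[:, v] = psf.full[:, r0:r0 + h, c0:c0 + w]
    if np.any(kernels < 0):
        raise ValueError("negative kernel values")
    return kernels
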