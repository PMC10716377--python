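"""Light-field view geometry: calibration, extraction, assembly.

A raw FLFM frame holds three sub-aperture views.  Before they can feed
the reconstruction networks the frame must be *realigned*: the in-plane
rotation of the lenslet arrangement relative to the sensor and the three
view centres are estimated once from a reference frame (a light field of
a bright, featureless sample), then every frame is derotated and cropped
into a (3, h, w) view stack.

Conventions (fixed so crops are bit-exact):

* 0-based pixel indices, origin at the top-left, coordinates (row, col);
* view ordering is canonical by angle from the +x axis (x -> +col,
  y -> -row), ties broken by distance from the sensor centre;
* rotation is applied about the sensor centre with bilinear
  interpolation and constant-0 boundary, and is skipped entirely when
  the calibrated rotation is zero so that extraction is a pure crop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate


class CalibrationError(ValueError):
    pass


@dataclass
class LFImage:
    """A raw 2D sensor light field."""

    data: np.ndarray
    pixel_pitch_um: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("LFImage data must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("LFImage contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("LFImage intensities must be nonnegative")


@dataclass
class ViewStack:
    """Three extracted sub-aperture views, shape (3, h, w)."""

    data: np.ndarray
    provenance: str = "raw"         # raw | denoised | synthetic

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] != 3:
            raise ValueError("ViewStack must have shape (3, h, w)")
        if np.any(self.data < 0):
            raise ValueError("ViewStack intensities must be nonnegative")


@dataclass
class CalibrationResult:
    """Realignment parameters for one instrument configuration."""

    rotation_degrees: float
    view_centers: np.ndarray        # (3, 2) [row, col] in the raw frame
    view_size: tuple[int, int]

    def __post_init__(self):
        self.view_centers = np.asarray(self.view_centers, dtype=float)
        if self.view_centers.shape != (3, 2):
            raise ValueError("view_centers must be (3, 2)")

    @classmethod
    def from_config(cls, config, view_size: tuple[int, int] | None = None
                    ) -> "CalibrationResult":
        """Ideal calibration for a simulated instrument (rotation 0)."""
        centers = config.view_centers_px
        if view_size is None:
            side = _default_view_side(centers, config.sensor_grid)
            view_size = (side, side)
        centers = _canonical_order(centers, config.sensor_grid)
        return cls(rotation_degrees=0.0, view_centers=centers,
                   view_size=tuple(view_size))

    def to_dict(self) -> dict:
        return {"rotation_degrees": float(self.rotation_degrees),
                "view_centers": self.view_centers.tolist(),
                "view_size": list(self.view_size)}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(rotation_degrees=d["rotation_degrees"],
                   view_centers=np.asarray(d["view_centers"]),
                   view_size=tuple(d["view_size"]))


def _default_view_side(centers: np.ndarray, sensor_grid) -> int:
    """Largest even square window keeping the three crops disjoint and
    inside the sensor."""
    dmin = min(np.hypot(*(centers[i] - centers[j]))
               for i in range(3) for j in range(i + 1, 3))
    border = min(min(r, sensor_grid[0] - 1 - r, c, sensor_grid[1] - 1 - c)
                 for r, c in centers)
    side = int(min(dmin / np.sqrt(2.0), 2 * border))
    return side - side % 2


def _angles_about_center(centers: np.ndarray, sensor_grid) -> np.ndarray:
    cy = sensor_grid[0] // 2
    cx = sensor_grid[1] // 2
    x = centers[:, 1] - cx
    y = cy - centers[:, 0]                     # image rows point down
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


def _canonical_order(centers: np.ndarray, sensor_grid) -> np.ndarray:
    ang = _angles_about_center(centers, sensor_grid)
    cy = (sensor_grid[0] - 1) / 2.0
    cx = (sensor_grid[1] - 1) / 2.0
    dist = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
    order = np.lexsort((dist, ang))
    return centers[order]


def calibrate(reference_lf: LFImage,
              view_size: tuple[int, int] | None = None,
              canonical_angles_deg=(90.0, 210.0, 330.0),
              threshold: float | None = None) -> CalibrationResult:
    """Estimate view centres and arrangement rotation from a reference LF.

    The reference is a light field of a uniformly bright sample: three
    illuminated discs.  Centres are intensity centroids of the connected
    components above ``threshold`` (default: 10% of the maximum), and
    the rotation is the mean circular offset of the measured component
    angles from the canonical arrangement angles, modulo the 120-degree
    symmetry, reported in (-60, 60] degrees.
    """
    img = reference_lf.data
    if threshold is None:
        threshold = 0.1 * img.max()
    labels, n = ndimage.label(img > threshold)
    if n != 3:
        raise CalibrationError(
            f"expected 3 illuminated sub-apertures, found {n} components")
    centers = np.asarray(ndimage.center_of_mass(img, labels, range(1, 4)))
    sensor_grid = img.shape
    centers = _canonical_order(centers, sensor_grid)
    ang = _angles_about_center(centers, sensor_grid)
    offs = []
    for a, a0 in zip(ang, canonical_angles_deg):
        d = np.mod(a - a0 + 60.0, 120.0) - 60.0
        offs.append(d)
    rotation = float(np.mean(offs))
    if view_size is None:
        side = _default_view_side(centers, sensor_grid)
        view_size = (side, side)
    return CalibrationResult(rotation_degrees=rotation, view_centers=centers,
                             view_size=tuple(view_size))


def _rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear rotation about the image centre, constant-0 boundary.

    Positive angle rotates image content counter-clockwise in the
    displayed (row-down) frame.
    """
    out = _sk_rotate(img, angle_deg, resize=False, center=None, order=1,
                     mode="constant", cval=0.0, preserve_range=True)
    return np.maximum(out, 0.0)


def _rotate_points(points: np.ndarray, angle_deg: float, shape) -> np.ndarray:
    """Rotate (row, col) points about the image centre by ``angle_deg``
    (same sense as :func:`_rotate_image` applied to content)."""
    cy = (shape[0] - 1) / 2.0
    cx = (shape[1] - 1) / 2.0
    th = np.deg2rad(angle_deg)
    x = points[:, 1] - cx
    y = cy - points[:, 0]
    xr = x * np.cos(th) - y * np.sin(th)
    yr = x * np.sin(th) + y * np.cos(th)
    return np.stack([cy - yr, cx + xr], axis=1)


def extract_views(lf: LFImage, cal: CalibrationResult) -> ViewStack:
    """Derotate the frame and crop the three view windows.

    At rotation 0 this is a pure integer crop (bit-exact); otherwise the
    frame is rotated by ``-rotation_degrees`` first and the calibrated
    centres are mapped into the derotated frame.
    """
    img = lf.data
    centers = cal.view_centers
    if abs(cal.rotation_degrees) > 1e-12:
        img = _rotate_image(img, -cal.rotation_degrees)
        centers = _rotate_points(centers, -cal.rotation_degrees, img.shape)
    h, w = cal.view_size
    out = np.empty((3, h, w))
    for v, (r, c) in enumerate(np.rint(centers).astype(int)):
        r0, c0 = r - h // 2, c - w // 2
        if r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
            raise ValueError(f"view {v} crop out of bounds")
        out[v] = img[r0:r0 + h, c0:c0 + w]
    return ViewStack(data=out, provenance="raw")


def assemble_lf(views: ViewStack, cal: CalibrationResult,
                sensor_grid: tuple[int, int] | None = None,
                pixel_pitch_um: float = 1.0) -> LFImage:
    """Inverse of :func:`extract_views`: paste views onto a zero sensor."""
    h, w = cal.view_size
    if views.data.shape[1:] != (h, w):
        raise ValueError(
            f"view shape {views.data.shape[1:]} does not match calibration "
            f"view_size {(h, w)}")
    centers = cal.view_centers
    if sensor_grid is None:
        rmax = int(np.ceil(centers[:, 0].max())) + h
        cmax = int(np.ceil(centers[:, 1].max())) + w
        sensor_grid = (rmax, cmax)
    canvas = np.zeros(sensor_grid)
    pts = centers
    if abs(cal.rotation_degrees) > 1e-12:
        pts = _rotate_points(centers, -cal.rotation_degrees, sensor_grid)
    for v, (r, c) in enumerate(np.rint(pts).astype(int)):
        r0, c0 = r - h // 2, c - w // 2
        canvas[r0:r0 + h, c0:c0 + w] = views.data[v]
    if abs(cal.rotation_degrees) > 1e-12:
        canvas = _rotate_image(canvas, cal.rotation_degrees)
    return LFImage(data=canvas, pixel_pitch_um=pixel_pitch_um)
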