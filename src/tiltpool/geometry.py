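"""Viewing geometry and groundtruth surface orientation from range maps.

A scene is a co-registered stereo pair of luminance images plus a per-pixel
range (distance) map.  Groundtruth tilt at a pixel is the orientation of
the range gradient, ``arctan2(∂r/∂y, ∂r/∂x)``, with the gradient computed
by Gaussian-derivative filtering (space constant ``sigma_tilt``, default
3 arcmin).  Slant is the angle between the line of sight and the surface,
``arctan(|∇_θ r| / r)`` with the gradient taken per radian of visual angle.

Coordinate convention: x increases rightward and y increases *upward* in
the visual field.  Arrays are stored bottom-row-first internally (row index
grows upward); the I/O layer flips top-row-first rasters on load.  With
this convention a ground plane receding in depth has tilt 90°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ARCMIN_PER_RAD",
    "ViewingGeometry",
    "RangeScene",
    "TiltMap",
    "gaussian_gradient",
    "tilt_from_range",
    "slant_from_range",
    "disparity_from_range",
]

ARCMIN_PER_RAD = 60.0 * 180.0 / np.pi

#: range-gradient magnitude (m per arcmin) below which tilt is undefined
GRADIENT_TOL = 1e-9

#: kernel truncation radius in units of the space constant
KERNEL_TRUNCATE = 3.0


@dataclass(frozen=True)
class ViewingGeometry:
    """Angular sampling and binocular viewing parameters.

    Parameters
    ----------
    pixel_scale : float
        Arcmin of visual angle per pixel.
    fixation_distance_m : float
        Distance to the fixation point; zero-disparity reference.
    ipd_cm : float
        Inter-pupillary distance, default the typical human 6.5 cm.
    image_size : tuple of int
        (rows, cols).
    """

    pixel_scale: float
    fixation_distance_m: float
    ipd_cm: float = 6.5
    image_size: tuple = (256, 256)

    def __post_init__(self):
        if self.pixel_scale <= 0 or self.ipd_cm <= 0 or self.fixation_distance_m <= 0:
            raise ValueError("pixel_scale, ipd_cm and fixation_distance_m must be > 0")

    @property
    def ipd_m(self) -> float:
        return self.ipd_cm / 100.0


@dataclass
class RangeScene:
    """Stereo luminance pair with co-registered range, bottom-row-first."""

    range_m: np.ndarray
    left_image: np.ndarray
    right_image: np.ndarray
    geometry: ViewingGeometry
    valid_mask: np.ndarray = None
    half_occlusion: np.ndarray = None

    def __post_init__(self):
        shape = self.range_m.shape
        for name in ("left_image", "right_image"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != shape:
                raise ValueError(f"{name} not co-registered with range map")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.range_m) & (self.range_m > 0)
        if np.any(self.range_m[self.valid_mask] <= 0):
            raise ValueError("range must be positive wherever valid")

    @property
    def shape(self):
        return self.range_m.shape


@dataclass
class TiltMap:
    """Groundtruth signed/unsigned tilt and slant per pixel."""

    tilt_signed: np.ndarray
    tilt_unsigned: np.ndarray
    slant: np.ndarray
    defined_mask: np.ndarray

    def __post_init__(self):
        ok = self.defined_mask
        if np.any((self.tilt_signed[ok] < 0) | (self.tilt_signed[ok] >= 360)):
            raise ValueError("tilt_signed out of [0, 360)")


def _border_margin(sigma_px: float) -> int:
    return int(np.ceil(KERNEL_TRUNCATE * sigma_px))


def _gradient_kernels(sigma_px: float):
    """Sampled Gaussian and Gaussian-derivative kernels, truncated at three
    space constants and normalized so that the smoothing kernel has unit sum
    and the derivative kernel responds with exactly unit slope to a ramp
    (making the operator exact on affine rasters despite truncation)."""
    r = int(np.ceil(KERNEL_TRUNCATE * sigma_px))
    u = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-0.5 * (u / sigma_px) ** 2)
    g = g / g.sum()
    d = u * np.exp(-0.5 * (u / sigma_px) ** 2)
    d = d / (u * d).sum()
    return g, d


def gaussian_gradient(raster, sigma_arcmin, geometry: ViewingGeometry):
    """Gaussian-derivative gradient of a raster, per arcmin of visual angle.

    Equivalent to smoothing with an isotropic 2D Gaussian of space constant
    ``sigma_arcmin`` and taking partial derivatives in x (rightward) and y
    (upward).  Returns ``(ddx, ddy, defined)`` where ``defined`` is False
    within a border margin of three space constants.
    """
    raster = np.asarray(raster, dtype=float)
    sigma_px = float(sigma_arcmin) / geometry.pixel_scale
    if sigma_px < 0.5:
        raise ValueError(
            f"sigma of {sigma_arcmin} arcmin is below half a pixel "
            f"({geometry.pixel_scale} arcmin/px)")
    g, d = _gradient_kernels(sigma_px)
    # axis 0 is y (upward), axis 1 is x; correlate1d differentiates along
    # increasing index, which matches both conventions here.
    ddx = ndimage.correlate1d(
        ndimage.correlate1d(raster, g, axis=0, mode="nearest"),
        d, axis=1, mode="nearest")
    ddy = ndimage.correlate1d(
        ndimage.correlate1d(raster, g, axis=1, mode="nearest"),
        d, axis=0, mode="nearest")
    ddx /= geometry.pixel_scale
    ddy /= geometry.pixel_scale
    defined = np.zeros(raster.shape, dtype=bool)
    m = _border_margin(sigma_px)
    if raster.shape[0] > 2 * m and raster.shape[1] > 2 * m:
        defined[m:raster.shape[0] - m, m:raster.shape[1] - m] = True
    return ddx, ddy, defined


def tilt_from_range(scene: RangeScene, sigma_tilt: float = 3.0) -> TiltMap:
    """Groundtruth tilt/slant from the range map.

    Tilt is the four-quadrant arctangent of the range gradient; pixels whose
    gradient magnitude is below tolerance (fronto-parallel surfaces) have no
    tilt direction and are marked undefined.
    """
    ddx, ddy, defined = gaussian_gradient(scene.range_m, sigma_tilt, scene.geometry)
    mag = np.hypot(ddx, ddy)
    tilt = np.rad2deg(np.arctan2(ddy, ddx)) % 360.0
    defined = defined & (mag >= GRADIENT_TOL) & scene.valid_mask
    slant = _slant_from_gradient(mag, scene.range_m)
    return TiltMap(tilt_signed=tilt, tilt_unsigned=tilt % 180.0,
                   slant=slant, defined_mask=defined)


def _slant_from_gradient(grad_mag_per_arcmin, range_m):
    grad_per_rad = np.asarray(grad_mag_per_arcmin) * ARCMIN_PER_RAD
    with np.errstate(divide="ignore", invalid="ignore"):
        slant = np.rad2deg(np.arctan(grad_per_rad / range_m))
    return np.nan_to_num(slant)


def slant_from_range(scene: RangeScene, sigma_tilt: float = 3.0):
    """Slant map: ``arctan(|∇_θ r| / r)``, 0 fronto-parallel, →90 grazing."""
    ddx, ddy, _ = gaussian_gradient(scene.range_m, sigma_tilt, scene.geometry)
    return _slant_from_gradient(np.hypot(ddx, ddy), scene.range_m)


def disparity_from_range(scene: RangeScene):
    """Relative binocular disparity in arcmin, positive = crossed (nearer).

    ``δ = IPD (1/r − 1/r_fix)`` radians, converted to arcmin.
    """
    geom = scene.geometry
    with np.errstate(divide="ignore"):
        delta_rad = geom.ipd_m * (1.0 / scene.range_m - 1.0 / geom.fixation_distance_m)
    return delta_rad * ARCMIN_PER_RAD
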