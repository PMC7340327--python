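"""Local image cues to 3D surface tilt.

Three cues feed the local estimator:

* **Luminance cue** -- orientation of the local luminance gradient,
  computed with Gaussian-derivative operators (space constant ``sigma_cue``,
  default 6 arcmin).
* **Disparity cue** -- orientation of the gradient of the binocular
  disparity map, which is itself recovered from the stereo pair by local
  windowed normalized cross-correlation (window space constant equal to the
  derivative operator's).
* **Texture cue** -- dominant orientation of the major axis of the local
  windowed amplitude spectrum.

Unsigned cues are the 180-degree modulus of the signed cues.  Each cue is
quantized into 64 equal half-open bins for lookup-table indexing.  Pixels
where a cue is undefined (flat windows, isotropic spectra, border margins,
failed left/right consistency) are excluded from training and estimation
rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (GRADIENT_TOL, KERNEL_TRUNCATE, RangeScene,
                       ViewingGeometry, disparity_from_range,
                       gaussian_gradient, _border_margin)

__all__ = [
    "CueMaps",
    "QuantizedCues",
    "orientation_cue",
    "compute_disparity",
    "texture_cue",
    "to_unsigned",
    "quantize",
    "dequantize",
    "compute_cue_maps",
]

N_CUE_BINS = 64

#: principal-axis eigenvalue ratio below which a spectrum counts as isotropic
ISOTROPY_RATIO = 1.05

#: left/right disparity disagreement (px) beyond which a pixel is half-occluded
LR_CONSISTENCY_PX = 1.0


@dataclass
class CueMaps:
    """Per-pixel signed/unsigned orientation cues and their validity masks."""

    lum_signed: np.ndarray
    lum_unsigned: np.ndarray
    tex_unsigned: np.ndarray
    disp_signed: np.ndarray
    disp_unsigned: np.ndarray
    disparity_map: np.ndarray        # arcmin
    lum_mask: np.ndarray
    tex_mask: np.ndarray
    disp_mask: np.ndarray
    half_occlusion: np.ndarray
    sigma_cue_arcmin: float = 6.0

    @property
    def all_defined(self):
        return self.lum_mask & self.tex_mask & self.disp_mask & ~self.half_occlusion


@dataclass
class QuantizedCues:
    """64-level bin indices for the three unsigned cues and the signed
    disparity cue, with a joint validity mask."""

    lum_u: np.ndarray
    tex_u: np.ndarray
    disp_u: np.ndarray
    disp_s: np.ndarray
    defined_mask: np.ndarray
    n_bins: int = N_CUE_BINS


def to_unsigned(signed_map):
    """Unsigned orientation: the 180-degree modulus of a signed cue."""
    return np.mod(signed_map, 180.0)


def quantize(values, n_bins: int = N_CUE_BINS, period: float = 180.0):
    """Bin index ``floor(value * n / period)`` over equal half-open bins."""
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v >= period)):
        raise ValueError(f"values must lie in [0, {period})")
    idx = np.floor(v * n_bins / period).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


def dequantize(indices, n_bins: int = N_CUE_BINS, period: float = 180.0):
    """Bin centre of each index."""
    idx = np.asarray(indices)
    return (idx + 0.5) * period / n_bins


def orientation_cue(raster, geometry: ViewingGeometry, sigma_cue: float = 6.0):
    """Signed orientation of the Gaussian-derivative gradient of a raster.

    Returns ``(orientation_deg in [0, 360), defined_mask)``; undefined where
    the gradient magnitude is negligible or within the border margin.
    """
    ddx, ddy, defined = gaussian_gradient(raster, sigma_cue, geometry)
    mag = np.hypot(ddx, ddy)
    ori = np.rad2deg(np.arctan2(ddy, ddx)) % 360.0
    scale = max(float(np.nanstd(np.asarray(raster, dtype=float))), 1.0)
    return ori, defined & (mag >= GRADIENT_TOL * scale)


# ---------------------------------------------------------------------------
# disparity estimation


def _gauss(im, sigma_px):
    return ndimage.gaussian_filter(im, sigma_px, truncate=KERNEL_TRUNCATE,
                                   mode="nearest")


def _shift_x(im, s):
    """``out(x) = im(x - s)`` with edge replication marked invalid."""
    out = np.empty_like(im)
    valid = np.zeros(im.shape, dtype=bool)
    if s == 0:
        return im.copy(), np.ones(im.shape, dtype=bool)
    if s > 0:
        out[:, s:] = im[:, :-s]
        out[:, :s] = im[:, :1]
        valid[:, s:] = True
    else:
        out[:, :s] = im[:, -s:]
        out[:, s:] = im[:, -1:]
        valid[:, :s] = True
    return out, valid


def _ncc_disparity(ref, other, shifts, sigma_px):
    """Per-pixel shift of ``other`` best matching ``ref`` under Gaussian-
    windowed normalized cross-correlation, with 3-point quadratic sub-pixel
    interpolation.  Convention: score(s) = NCC(ref(x), other(x - s))."""
    eps = 1e-12
    m_ref = _gauss(ref, sigma_px)
    v_ref = np.maximum(_gauss(ref * ref, sigma_px) - m_ref ** 2, 0.0)
    scores = np.full((len(shifts),) + ref.shape, -np.inf)
    for i, s in enumerate(shifts):
        oth, valid = _shift_x(other, s)
        m2 = _gauss(oth, sigma_px)
        v2 = np.maximum(_gauss(oth * oth, sigma_px) - m2 ** 2, 0.0)
        cov = _gauss(ref * oth, sigma_px) - m_ref * m2
        ncc = cov / np.sqrt(np.maximum(v_ref * v2, eps))
        ncc[~valid] = -np.inf
        scores[i] = ncc
    best = np.argmax(scores, axis=0)
    flat = v_ref < eps * np.maximum(np.abs(ref).max() ** 2, 1.0)
    # quadratic sub-pixel refinement around the integer peak
    ii, jj = np.indices(ref.shape)
    c0 = scores[np.clip(best - 1, 0, len(shifts) - 1), ii, jj]
    c1 = scores[best, ii, jj]
    c2 = scores[np.clip(best + 1, 0, len(shifts) - 1), ii, jj]
    interior = (best > 0) & (best < len(shifts) - 1) & np.isfinite(c0) & np.isfinite(c2)
    c0s = np.where(interior, c0, 0.0)
    c2s = np.where(interior, c2, 0.0)
    denom = c0s - 2 * np.where(np.isfinite(c1), c1, 0.0) + c2s
    safe = interior & (np.abs(denom) > eps)
    frac = np.where(safe, 0.5 * (c0s - c2s) / np.where(safe, denom, 1.0), 0.0)
    # NCC == 1 only at an exact match: integer shift is already exact there
    frac = np.where(c1 >= 1.0 - 1e-9, 0.0, frac)
    frac = np.clip(frac, -0.5, 0.5)
    disp = np.asarray(shifts)[best] + frac
    defined = np.isfinite(c1) & ~flat
    return disp, defined


def compute_disparity(left, right, geometry: ViewingGeometry,
                      sigma_cue: float = 6.0, search_range_px=None):
    """Binocular disparity by Gaussian-windowed normalized cross-correlation.

    Returns ``(disparity_arcmin, half_occlusion_mask, defined_mask)``.

    Convention: disparity ``d`` at pixel x satisfies
    ``left(x) ~ right(x - d)``, so a right image globally shifted by +3 px
    yields d = -3 px.  Positive disparity is crossed (nearer than fixation)
    for scenes rendered by :mod:`tiltpool.synthetic`.  Pixels disagreeing by
    more than 1 px in the left/right consistency check are flagged
    half-occluded.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    sigma_px = sigma_cue / geometry.pixel_scale
    if search_range_px is None:
        search_range_px = _default_search_range(geometry)
    lo, hi = int(np.floor(search_range_px[0])), int(np.ceil(search_range_px[1]))
    shifts = list(range(lo - 2, hi + 3))  # 2 px margin each side
    d_left, def_l = _ncc_disparity(left, right, shifts, sigma_px)
    # right->left: left(x + s) matches right(x); at corresponding points
    # s = d, so consistency requires d_right(x - d_left(x)) ~ d_left(x)
    d_right, def_r = _ncc_disparity(right, left, [-s for s in shifts][::-1], sigma_px)
    d_right = -d_right
    cols = np.arange(left.shape[1])
    xr = np.clip(np.round(cols[None, :] - d_left).astype(int), 0, left.shape[1] - 1)
    rows = np.arange(left.shape[0])[:, None]
    mismatch = np.abs(d_right[rows, xr] - d_left)
    half_occ = (mismatch > LR_CONSISTENCY_PX) | ~def_r[rows, xr]
    margin = _border_margin(sigma_px)
    border = np.zeros(left.shape, dtype=bool)
    if left.shape[0] > 2 * margin and left.shape[1] > 2 * margin:
        border[margin:-margin, margin:-margin] = True
    defined = def_l & border
    return d_left * geometry.pixel_scale, half_occ, defined


def _default_search_range(geometry: ViewingGeometry,
                          distance_bounds_m=(3.0, 1e6)):
    """Disparity search bounds (px) implied by scene distance limits."""
    from .geometry import ARCMIN_PER_RAD
    d_near = geometry.ipd_m * (1.0 / distance_bounds_m[0]
                               - 1.0 / geometry.fixation_distance_m) * ARCMIN_PER_RAD
    d_far = geometry.ipd_m * (1.0 / distance_bounds_m[1]
                              - 1.0 / geometry.fixation_distance_m) * ARCMIN_PER_RAD
    lo = min(d_near, d_far) / geometry.pixel_scale
    hi = max(d_near, d_far) / geometry.pixel_scale
    return lo, hi


# ---------------------------------------------------------------------------
# texture cue


def _patch_size(sigma_px: float) -> int:
    support = 2 * int(np.ceil(KERNEL_TRUNCATE * sigma_px)) + 1
    return int(2 ** np.ceil(np.log2(support)))


def texture_cue(image, geometry: ViewingGeometry, window_sigma: float = 6.0,
                chunk: int = 2048):
    """Dominant orientation of the local amplitude spectrum, in [0, 180).

    Per pixel, a Gaussian-tapered patch (space constant ``window_sigma``,
    truncated at three space constants, power-of-two side) is Fourier
    transformed; the orientation is the major principal axis of the
    amplitude spectrum's second-moment matrix (DC removed), mapped directly
    to the image domain (a grating modulated along direction theta has its
    spectral energy along frequency direction theta).  Patches whose
    spectral principal-axis ratio is below 1.05 are undefined (isotropic).
    """
    image = np.asarray(image, dtype=float)
    sigma_px = window_sigma / geometry.pixel_scale
    P = _patch_size(sigma_px)
    half = P // 2
    rows, cols = image.shape
    ori = np.zeros(image.shape)
    defined = np.zeros(image.shape, dtype=bool)
    if rows <= P or cols <= P:
        return ori, defined

    yy, xx = np.mgrid[0:P, 0:P].astype(float)
    taper = np.exp(-0.5 * (((xx - half) / sigma_px) ** 2
                           + ((yy - half) / sigma_px) ** 2))
    fx = np.fft.fftfreq(P)[None, :]
    fy = np.fft.fftfreq(P)[:, None]
    fx2, fy2, fxy = fx ** 2 + 0 * fy, fy ** 2 + 0 * fx, fx * fy

    windows = np.lib.stride_tricks.sliding_window_view(image, (P, P))
    wr, wc = windows.shape[:2]
    flat = windows.reshape(-1, P, P)
    out_ori = np.empty(flat.shape[0])
    out_def = np.empty(flat.shape[0], dtype=bool)
    for start in range(0, flat.shape[0], chunk):
        blk = flat[start:start + chunk] * taper
        spec = np.abs(np.fft.fft2(blk))
        spec[:, 0, 0] = 0.0  # remove DC
        mxx = np.einsum("kij,ij->k", spec, fx2)
        myy = np.einsum("kij,ij->k", spec, fy2)
        mxy = np.einsum("kij,ij->k", spec, fxy)
        tr = mxx + myy
        disc = np.sqrt(np.maximum((mxx - myy) ** 2 + 4 * mxy ** 2, 0.0))
        lam_max = 0.5 * (tr + disc)
        lam_min = 0.5 * (tr - disc)
        ratio = lam_max / np.maximum(lam_min, 1e-15)
        ang = 0.5 * np.rad2deg(np.arctan2(2 * mxy, mxx - myy))
        out_ori[start:start + chunk] = np.mod(ang, 180.0)
        out_def[start:start + chunk] = (tr > 1e-12) & (ratio >= ISOTROPY_RATIO)
    # frequency axis 0 corresponds to array axis 0 = y upward: arctan2 above
    # already uses (fy, fx) ordering via the moment matrix, so the angle is
    # the image-domain modulation direction.
    r0 = half
    ori[r0:r0 + wr, r0:r0 + wc] = out_ori.reshape(wr, wc)
    defined[r0:r0 + wr, r0:r0 + wc] = out_def.reshape(wr, wc)
    return ori, defined


# ---------------------------------------------------------------------------
# orchestration


def compute_cue_maps(scene: RangeScene, sigma_cue: float = 6.0,
                     search_range_px=None, disparity_groundtruth=None) -> CueMaps:
    """All three cues for a scene.

    ``disparity_groundtruth`` (arcmin) bypasses stereo matching when the
    true disparity map is available (useful for isolating downstream
    stages); otherwise disparity is estimated from the stereo pair.
    """
    geom = scene.geometry
    lum_s, lum_m = orientation_cue(scene.left_image, geom, sigma_cue)
    tex_u, tex_m = texture_cue(scene.left_image, geom, sigma_cue)
    if disparity_groundtruth is not None:
        disp_map = np.asarray(disparity_groundtruth, dtype=float)
        half_occ = np.zeros(scene.shape, dtype=bool)
        disp_def = np.ones(scene.shape, dtype=bool)
    else:
        if search_range_px is None:
            gt = disparity_from_range(scene) / geom.pixel_scale
            search_range_px = (float(np.nanmin(gt)), float(np.nanmax(gt)))
        disp_map, half_occ, disp_def = compute_disparity(
            scene.left_image, scene.right_image, geom, sigma_cue,
            search_range_px=search_range_px)
    disp_s, disp_grad_m = orientation_cue(disp_map, geom, sigma_cue)
    if scene.half_occlusion is not None:
        half_occ = half_occ | scene.half_occlusion
    return CueMaps(
        lum_signed=lum_s, lum_unsigned=to_unsigned(lum_s),
        tex_unsigned=tex_u,
        disp_signed=disp_s, disp_unsigned=to_unsigned(disp_s),
        disparity_map=disp_map,
        lum_mask=lum_m, tex_mask=tex_m,
        disp_mask=disp_grad_m & disp_def,
        half_occlusion=half_occ,
        sigma_cue_arcmin=sigma_cue)


def quantize_cues(cues: CueMaps, n_bins: int = N_CUE_BINS) -> QuantizedCues:
    """Quantize a :class:`CueMaps` into lookup-table bin indices."""
    return QuantizedCues(
        lum_u=quantize(cues.lum_unsigned, n_bins, 180.0),
        tex_u=quantize(cues.tex_unsigned, n_bins, 180.0),
        disp_u=quantize(cues.disp_unsigned, n_bins, 180.0),
        disp_s=quantize(cues.disp_signed, n_bins, 360.0),
        defined_mask=cues.all_defined,
        n_bins=n_bins)
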