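"""Stage 2: spatial pooling of local tilt estimates.

A global tilt estimate at a target pixel is the weighted circular mean
(period 360) of the local estimates inside a spatial neighborhood centred
on the target.  Two neighborhood families are provided:

* **fixed circular** -- one diameter for every target, equal weights;
* **adaptive elliptical** -- per-target-tilt ellipses whose relative area,
  aspect ratio and orientation come from a :class:`~tiltpool.statistics.
  PoolingSpec` fit to scene statistics, scaled so the average ellipse area
  matches a circle of the requested average equivalent diameter.

The adaptive region can be keyed on the groundtruth tilt at the target
(oracle analysis) or on the local estimate at the target (single pass, no
iteration).  A zero-diameter region degenerates to the single target pixel,
so the global model reduces exactly to the local model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circstats import DegenerateResultantError, circ_mean
from .geometry import ViewingGeometry
from .lut import LocalEstimateMap
from .statistics import PoolingSpec

__all__ = [
    "PoolingRegion",
    "circular_region",
    "elliptical_region",
    "pool",
    "estimate_global",
]


@dataclass
class PoolingRegion:
    """Pixel offsets (dx, dy) and normalized weights of a pooling region."""

    offsets: np.ndarray   # (N, 2) ints: (dx, dy), includes (0, 0)
    weights: np.ndarray   # non-negative, sums to 1
    shape: dict = None

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if not ((self.offsets == 0).all(axis=1)).any():
            raise ValueError("region must contain the target offset (0, 0)")


def _region_from_mask(dx, dy, inside, shape_info, weights="uniform",
                      taper_sigma_px=None):
    inside = inside.copy()
    c = inside.shape[0] // 2
    inside[c, c] = True  # always contains the target
    offs = np.column_stack([dx[inside], dy[inside]]).astype(int)
    if weights == "uniform":
        w = np.ones(len(offs))
    elif weights == "gaussian":
        sig = taper_sigma_px if taper_sigma_px else max(np.abs(offs).max() / 2.0, 1.0)
        w = np.exp(-0.5 * (offs[:, 0] ** 2 + offs[:, 1] ** 2) / sig ** 2)
    else:
        raise ValueError(f"unknown weights {weights!r}")
    return PoolingRegion(offsets=offs, weights=w / w.sum(), shape=shape_info)


def circular_region(diameter_arcmin: float, geometry: ViewingGeometry,
                    weights: str = "uniform") -> PoolingRegion:
    """Equal-weight circular region of the given diameter (arcmin).

    Membership is a centre-in-circle test on the pixel lattice; a diameter
    smaller than one pixel gives the single-pixel region (the local model).
    """
    if diameter_arcmin < 0:
        raise ValueError("diameter must be >= 0")
    radius_px = diameter_arcmin / 2.0 / geometry.pixel_scale
    r = int(np.floor(radius_px))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = dx ** 2 + dy ** 2 <= radius_px ** 2
    return _region_from_mask(dx, dy, inside,
                             {"kind": "circle", "diameter_arcmin": diameter_arcmin},
                             weights)


def elliptical_region(target_tilt_deg: float, dbar_arcmin: float,
                      spec: PoolingSpec, geometry: ViewingGeometry,
                      weights: str = "uniform") -> PoolingRegion:
    """Adaptive elliptical region for a target tilt at average equivalent
    diameter ``dbar_arcmin``.

    The bin's relative area scales the circle area ``pi (D/2)^2`` so the
    mean area across bins equals the matched circle's; aspect ratio and
    orientation come from the spec.
    """
    if dbar_arcmin < 0:
        raise ValueError("average equivalent diameter must be >= 0")
    b = int(spec.bin_of(target_tilt_deg))
    area = spec.relative_area[b] * np.pi * (dbar_arcmin / 2.0) ** 2
    aspect = spec.aspect_ratio[b]
    phi = np.deg2rad(spec.orientation[b])
    area_px = area / geometry.pixel_scale ** 2
    a = np.sqrt(area_px * aspect / np.pi)       # semi-major, px
    bmin = np.sqrt(area_px / (np.pi * aspect))  # semi-minor, px
    r = int(np.floor(max(a, bmin)))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = (u / max(a, 1e-9)) ** 2 + (v / max(bmin, 1e-9)) ** 2 <= 1.0
    return _region_from_mask(
        dx, dy, inside,
        {"kind": "ellipse", "area_arcmin2": float(area), "aspect": float(aspect),
         "orientation_deg": float(np.rad2deg(phi) % 180.0), "bin": b},
        weights)


def pool(local_map: LocalEstimateMap, region: PoolingRegion, target_rc):
    """Weighted circular mean of the local estimates covered by the region.

    Undefined local estimates (and out-of-image offsets) are dropped and the
    weights renormalized.  Returns ``(estimate_deg, flag)`` where flag is
    ``"ok"``, ``"degenerate"`` (resultant collapsed; falls back to the local
    estimate at the target) or ``"undefined"`` (no covered estimates).
    """
    r0, c0 = target_rc
    rows, cols = local_map.tilt_estimate.shape
    if len(region.offsets) == 1:
        if local_map.defined_mask[r0, c0]:
            return float(local_map.tilt_estimate[r0, c0]), "ok"
        return np.nan, "undefined"
    rr = r0 + region.offsets[:, 1]   # dy along axis 0
    cc = c0 + region.offsets[:, 0]
    ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
    rr, cc, w = rr[ok], cc[ok], region.weights[ok]
    defined = local_map.defined_mask[rr, cc]
    if not np.any(defined):
        return np.nan, "undefined"
    angles = local_map.tilt_estimate[rr[defined], cc[defined]]
    try:
        summary = circ_mean(angles, w[defined], period=360.0)
    except DegenerateResultantError:
        if local_map.defined_mask[r0, c0]:
            return float(local_map.tilt_estimate[r0, c0]), "degenerate"
        return np.nan, "undefined"
    return summary.mean_angle, "ok"


def _pool_many(local_map, region, targets):
    """Vectorized pooling of one region over many target pixels."""
    targets = np.asarray(targets, dtype=int)
    rows, cols = local_map.tilt_estimate.shape
    if len(region.offsets) == 1:
        # single-pixel region: the global model IS the local model, exactly
        t_def = local_map.defined_mask[targets[:, 0], targets[:, 1]]
        vals = local_map.tilt_estimate[targets[:, 0], targets[:, 1]].astype(float)
        return np.where(t_def, vals, np.nan)
    rr = targets[:, 0][:, None] + region.offsets[None, :, 1]
    cc = targets[:, 1][:, None] + region.offsets[None, :, 0]
    inb = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
    rr_c = np.clip(rr, 0, rows - 1)
    cc_c = np.clip(cc, 0, cols - 1)
    use = inb & local_map.defined_mask[rr_c, cc_c]
    w = np.where(use, region.weights[None, :], 0.0)
    z = np.where(use, np.exp(1j * np.deg2rad(local_map.tilt_estimate[rr_c, cc_c])), 0)
    zsum = (w * z).sum(axis=1)
    wsum = w.sum(axis=1)
    from .circstats import wrap_angle
    est = wrap_angle(np.rad2deg(np.angle(zsum)), 360.0)
    degenerate = np.abs(zsum) < 1e-9 * np.maximum(wsum, 1e-300)
    # degenerate resultant: fall back to the local estimate at the target
    t_def = local_map.defined_mask[targets[:, 0], targets[:, 1]]
    local_at = local_map.tilt_estimate[targets[:, 0], targets[:, 1]]
    est = np.where(degenerate & t_def, local_at, est)
    est = np.where(wsum <= 0, np.nan, est)
    est = np.where(degenerate & ~t_def, np.nan, est)
    return est


def estimate_global(local_map: LocalEstimateMap, geometry: ViewingGeometry,
                    mode: str = "fixed", diameter_arcmin: float = 60.0,
                    spec: PoolingSpec = None, key_mode: str = "groundtruth",
                    key_tilt=None, targets=None, weights: str = "uniform"):
    """Global tilt estimates by pooling a local-estimate map.

    Parameters
    ----------
    mode : "fixed" or "adaptive"
        Fixed circular pooling at ``diameter_arcmin``, or adaptive
        elliptical pooling at average equivalent diameter ``diameter_arcmin``
        using ``spec``.
    key_mode : "groundtruth" or "local_estimate"
        What the adaptive region is keyed on.  ``key_tilt`` must be the
        groundtruth tilt map for "groundtruth"; for "local_estimate" the
        region is keyed on the *initial* local estimate at each target
        (single pass).
    targets : (N, 2) int array of (row, col), or None
        Targets to evaluate; None means every pixel.

    Returns an array of pooled estimates (NaN where undefined): a map if
    ``targets`` is None, else one value per target row.
    """
    rows, cols = local_map.tilt_estimate.shape
    as_map = targets is None
    if as_map:
        rr, cc = np.mgrid[0:rows, 0:cols]
        targets = np.column_stack([rr.ravel(), cc.ravel()])
    targets = np.asarray(targets, dtype=int)

    if mode == "fixed":
        region = circular_region(diameter_arcmin, geometry, weights)
        out = _pool_many(local_map, region, targets)
    elif mode == "adaptive":
        if spec is None:
            raise ValueError("adaptive pooling requires a PoolingSpec")
        if key_mode == "groundtruth":
            if key_tilt is None:
                raise ValueError("groundtruth keying requires key_tilt")
            keys = np.asarray(key_tilt)[targets[:, 0], targets[:, 1]]
        elif key_mode == "local_estimate":
            keys = local_map.tilt_estimate[targets[:, 0], targets[:, 1]]
        else:
            raise ValueError(f"unknown key_mode {key_mode!r}")
        out = np.full(len(targets), np.nan)
        bins = spec.bin_of(keys)
        for b in np.unique(bins):
            sel = bins == b
            center = (b + 0.5) * 360.0 / spec.n_bins
            region = elliptical_region(center, diameter_arcmin, spec,
                                       geometry, weights)
            out[sel] = _pool_many(local_map, region, targets[sel])
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")

    if as_map:
        return out.reshape(rows, cols)
    return out
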