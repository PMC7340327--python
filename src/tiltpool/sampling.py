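"""Stimulus sampling: constraint filters and tilt-balanced selection.

Scene locations become experimental stimuli only if the surface at the
centre pixel is measurable and displayable: slant within bounds (default
30-75 deg; the restricted variant uses 30-60), distance within 5-50 m, not
half-occluded, and the RMS contrast of the 3-degree aperture within 5-40%.
Surviving candidates are then sampled without replacement so that every
15-degree tilt bin (24 bins over the full circle) contributes the same
number of stimuli (150 per bin in the original design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import RangeScene, TiltMap, ViewingGeometry

__all__ = ["PatchConstraints", "rms_contrast", "filter_patches",
           "balanced_sample"]


@dataclass(frozen=True)
class PatchConstraints:
    """Acceptance intervals for stimulus patches (closed on both ends)."""

    slant_range_deg: tuple = (30.0, 75.0)
    distance_range_m: tuple = (5.0, 50.0)
    contrast_range_pct: tuple = (5.0, 40.0)
    exclude_half_occluded: bool = True
    aperture_diameter_deg: float = 3.0

    def __post_init__(self):
        for lo, hi in (self.slant_range_deg, self.distance_range_m,
                       self.contrast_range_pct):
            if lo > hi:
                raise ValueError("constraint ranges must be non-empty")
        if self.aperture_diameter_deg <= 0:
            raise ValueError("aperture must be > 0")


def rms_contrast(patch_luminance, aperture_mask=None) -> float:
    """RMS contrast in percent: 100 * (std / mean) within the aperture."""
    lum = np.asarray(patch_luminance, dtype=float)
    if aperture_mask is not None:
        lum = lum[np.asarray(aperture_mask, dtype=bool)]
    mean = lum.mean()
    if mean <= 0:
        raise ValueError("mean luminance must be positive")
    return float(100.0 * lum.std() / mean)


def _aperture_mask(radius_px: float):
    r = int(np.ceil(radius_px))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    return dx ** 2 + dy ** 2 <= radius_px ** 2, r


def _tilt_bin(tilt_deg, n_bins=24):
    return (np.floor(np.mod(tilt_deg, 360.0) * n_bins / 360.0)
            .astype(int) % n_bins)


def filter_patches(candidates, constraints: PatchConstraints,
                   tilt_map: TiltMap, range_map, luminance,
                   occlusion_mask, geometry: ViewingGeometry,
                   scene_id=0, n_bins: int = 24) -> pd.DataFrame:
    """Apply the four stimulus-exclusion rules to candidate centre pixels.

    A candidate survives iff its centre-pixel slant, distance and occlusion
    status, and the aperture's RMS contrast, all fall in the (closed)
    acceptance intervals, and groundtruth tilt is defined at the centre.
    Returns a manifest frame (scene, row, col, tilt, slant, distance,
    contrast, bin).
    """
    radius_px = constraints.aperture_diameter_deg * 60.0 / 2.0 / geometry.pixel_scale
    ap_mask, r = _aperture_mask(radius_px)
    rows_lim, cols_lim = np.asarray(range_map).shape
    recs = []
    for (row, col) in candidates:
        if not (0 <= row < rows_lim and 0 <= col < cols_lim):
            raise ValueError(f"candidate {(row, col)} outside image bounds")
        if not tilt_map.defined_mask[row, col]:
            continue
        slant = float(tilt_map.slant[row, col])
        dist = float(np.asarray(range_map)[row, col])
        lo, hi = constraints.slant_range_deg
        if not lo <= slant <= hi:
            continue
        lo, hi = constraints.distance_range_m
        if not lo <= dist <= hi:
            continue
        if constraints.exclude_half_occluded and occlusion_mask is not None \
                and occlusion_mask[row, col]:
            continue
        r0, r1 = max(0, row - r), min(rows_lim, row + r + 1)
        c0, c1 = max(0, col - r), min(cols_lim, col + r + 1)
        patch = np.asarray(luminance)[r0:r1, c0:c1]
        sub = ap_mask[r0 - (row - r):ap_mask.shape[0] - ((row + r + 1) - r1),
                      c0 - (col - r):ap_mask.shape[1] - ((col + r + 1) - c1)]
        contrast = rms_contrast(patch, sub)
        lo, hi = constraints.contrast_range_pct
        if not lo <= contrast <= hi:
            continue
        tilt = float(tilt_map.tilt_signed[row, col])
        recs.append(dict(scene=scene_id, row=row, col=col, tilt=tilt,
                         slant=slant, distance=dist, contrast=contrast,
                         bin=int(_tilt_bin(tilt, n_bins))))
    return pd.DataFrame(
        recs, columns=["scene", "row", "col", "tilt", "slant", "distance",
                       "contrast", "bin"])


def balanced_sample(survivors: pd.DataFrame, n_bins: int = 24,
                    per_bin: int = 150, seed: int = 0) -> pd.DataFrame:
    """Uniform random selection without replacement of ``per_bin`` patches
    from every centre-tilt bin; errors name any undersupplied bin."""
    rng = np.random.default_rng(seed)
    parts = []
    for b in range(n_bins):
        pool = survivors[survivors["bin"] == b]
        if len(pool) < per_bin:
            raise ValueError(
                f"bin {b} has only {len(pool)} survivors "
                f"(deficit {per_bin - len(pool)})")
        take = rng.choice(len(pool), size=per_bin, replace=False)
        parts.append(pool.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)
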