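"""Spatial statistics of surface tilt and the elliptical pooling fits.

Tilt in real scenes is spatially correlated: the mean absolute circular
difference between the tilt at a target pixel and the tilt at an offset
grows with spatial separation, and when conditioned on the target tilt the
iso-difference contours become elliptical -- elongated orthogonally to the
tilt direction.  This module computes those difference maps, fits a 2D
Gaussian to the (inverted, unit-volume) similarity surface, and converts
per-tilt fits into the pooling specification used by the adaptive
elliptical pooling model: relative area, aspect ratio, and orientation per
target-tilt bin, together with the average equivalent pooling diameter
``D = 2 sqrt(A/pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .circstats import abs_diff
from .geometry import TiltMap

__all__ = [
    "DiffMap",
    "EllipseFit",
    "PoolingSpec",
    "tilt_prior_histogram",
    "mean_diff_map",
    "fit_pooling_ellipse",
    "equivalent_diameter",
    "pooling_spec_from_stats",
]


@dataclass
class DiffMap:
    """Mean absolute tilt difference on a grid of spatial offsets.

    ``mean_abs_diff[i, j]`` is the aggregate over all valid (target,
    neighbor) pairs at offset ``(offsets_x[j], offsets_y[i])`` arcmin;
    NaN marks offsets with no pairs.
    """

    offsets_x: np.ndarray   # arcmin, ascending
    offsets_y: np.ndarray   # arcmin, ascending (upward)
    mean_abs_diff: np.ndarray
    n_pairs: np.ndarray
    condition: object = "all"   # "all" or target-tilt bin index
    pixel_scale: float = 1.0


@dataclass
class EllipseFit:
    """2D-Gaussian fit to a tilt-similarity surface."""

    covariance: np.ndarray          # arcmin^2, 2x2 SPD
    orientation: float              # deg in [0, 180), major axis
    aspect_ratio: float             # sqrt(lam_max / lam_min) >= 1
    area: float                     # arcmin^2 of the 1-sigma ellipse
    equivalent_diameter: float      # arcmin
    condition: object = "all"

    @classmethod
    def from_covariance(cls, cov, condition="all"):
        cov = np.asarray(cov, dtype=float)
        lam, vec = np.linalg.eigh(cov)
        if lam[0] <= 0:
            raise ValueError("fitted covariance is not positive definite")
        major = vec[:, 1]
        orientation = np.rad2deg(np.arctan2(major[1], major[0])) % 180.0
        aspect = float(np.sqrt(lam[1] / lam[0]))
        area = float(np.pi * np.sqrt(np.linalg.det(cov)))
        return cls(covariance=cov, orientation=float(orientation),
                   aspect_ratio=aspect, area=area,
                   equivalent_diameter=equivalent_diameter(area),
                   condition=condition)


@dataclass
class PoolingSpec:
    """Per-tilt-bin pooling-region parameters, areas normalized to mean 1."""

    n_bins: int
    relative_area: np.ndarray     # mean 1 across bins
    aspect_ratio: np.ndarray
    orientation: np.ndarray       # deg in [0, 180)
    fitted_dbar: float            # arcmin: average equivalent diameter of fits

    @property
    def bin_centers(self):
        return (np.arange(self.n_bins) + 0.5) * 360.0 / self.n_bins

    def bin_of(self, tilt_deg):
        return (np.floor(np.mod(tilt_deg, 360.0) * self.n_bins / 360.0)
                .astype(int) % self.n_bins)

    @classmethod
    def isotropic(cls, n_bins: int = 24, dbar: float = 60.0):
        """Spec of identical circles: adaptive pooling degenerates to fixed."""
        return cls(n_bins=n_bins, relative_area=np.ones(n_bins),
                   aspect_ratio=np.ones(n_bins),
                   orientation=np.zeros(n_bins), fitted_dbar=dbar)


def tilt_prior_histogram(tilt_maps, n_bins: int = 24, period: float = 360.0):
    """Normalized histogram of defined tilts over equal-width bins."""
    counts = np.zeros(n_bins)
    edges = np.linspace(0.0, period, n_bins + 1)
    total = 0
    for tm in tilt_maps:
        tilt = tm.tilt_signed if isinstance(tm, TiltMap) else np.asarray(tm)
        mask = tm.defined_mask if isinstance(tm, TiltMap) else np.isfinite(tilt)
        vals = np.mod(tilt[mask], period)
        counts += np.histogram(vals, bins=edges)[0]
        total += vals.size
    if total == 0:
        raise ValueError("no defined tilt values")
    return counts / counts.sum()


def _as_tilt_and_mask(tm):
    if isinstance(tm, TiltMap):
        return tm.tilt_signed, tm.defined_mask
    tilt = np.asarray(tm, dtype=float)
    return tilt, np.isfinite(tilt)


def mean_diff_map(tilt_maps, max_offset_arcmin: float, pixel_scale: float = 1.0,
                  condition_bin=None, n_bins: int = 24,
                  aggregation: str = "circular") -> DiffMap:
    """Mean absolute tilt difference as a function of spatial offset.

    For each offset within ``max_offset_arcmin``, aggregates the absolute
    circular difference between the tilt at every valid target pixel and the
    tilt at the offset neighbor, over all supplied maps.  When
    ``condition_bin`` is given, targets are restricted to that signed-tilt
    bin (of ``n_bins`` 15-degree bins by default).  The default aggregation
    is the circular mean of the absolute differences; ``"arithmetic"`` uses
    the plain mean.
    """
    if isinstance(tilt_maps, (TiltMap, np.ndarray)):
        tilt_maps = [tilt_maps]
    r = int(np.floor(max_offset_arcmin / pixel_scale))
    if r < 1:
        raise ValueError("max_offset must cover at least one pixel")
    size = 2 * r + 1
    phasor = np.zeros((size, size), dtype=np.complex128)
    lin = np.zeros((size, size))
    npairs = np.zeros((size, size), dtype=np.int64)

    for tm in tilt_maps:
        tilt, defined = _as_tilt_and_mask(tm)
        if condition_bin is not None:
            bins = np.floor(np.mod(tilt, 360.0) * n_bins / 360.0).astype(int)
            target_ok = defined & (bins == int(condition_bin))
        else:
            target_ok = defined
        rows, cols = tilt.shape
        for iy, dy in enumerate(range(-r, r + 1)):
            for ix, dx in enumerate(range(-r, r + 1)):
                if condition_bin is None and (dy, dx) < (0, 0):
                    continue  # filled by mirror symmetry below
                # neighbor at (x+dx, y+dy); axis 0 is y upward
                t_r0, t_r1 = max(0, -dy), min(rows, rows - dy)
                t_c0, t_c1 = max(0, -dx), min(cols, cols - dx)
                if t_r0 >= t_r1 or t_c0 >= t_c1:
                    continue
                tgt = np.s_[t_r0:t_r1, t_c0:t_c1]
                nbr = np.s_[t_r0 + dy:t_r1 + dy, t_c0 + dx:t_c1 + dx]
                m = target_ok[tgt] & defined[nbr]
                if not np.any(m):
                    continue
                d = abs_diff(tilt[nbr][m], tilt[tgt][m], 360.0)
                phasor[iy, ix] += np.exp(1j * np.deg2rad(d)).sum()
                lin[iy, ix] += d.sum()
                npairs[iy, ix] += int(m.sum())

    if condition_bin is None:
        # the unconditioned statistic is exactly symmetric under pair
        # exchange: mirror each computed offset to its negation
        phasor = np.where(npairs > 0, phasor, phasor[::-1, ::-1])
        lin = np.where(npairs > 0, lin, lin[::-1, ::-1])
        npairs = np.maximum(npairs, npairs[::-1, ::-1])

    from .circstats import wrap_angle
    with np.errstate(invalid="ignore"):
        if aggregation == "circular":
            vals = wrap_angle(np.rad2deg(np.angle(phasor)), 360.0)
        elif aggregation == "arithmetic":
            vals = lin / np.maximum(npairs, 1)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    vals = np.where(npairs > 0, vals, np.nan)
    offs = np.arange(-r, r + 1) * pixel_scale
    return DiffMap(offsets_x=offs, offsets_y=offs, mean_abs_diff=vals,
                   n_pairs=npairs,
                   condition="all" if condition_bin is None else int(condition_bin),
                   pixel_scale=pixel_scale)


def fit_pooling_ellipse(diff_map: DiffMap) -> EllipseFit:
    """Fit a centred 2D Gaussian to the tilt-similarity surface.

    The difference map is minimal at the centre, so the *inverted* surface
    ``s = max(diff) - diff`` (maximal where tilts are most similar) is
    normalized to unit volume and fit by ``A exp(-0.5 u' Sigma^-1 u)`` in a
    least-squares sense over the valid offsets.  The ellipse parameters
    (orientation of the major axis, aspect ratio, area of the one-sigma
    iso-level ``A = pi sqrt(det Sigma)``) come from the fitted covariance.
    """
    vals = diff_map.mean_abs_diff
    ok = np.isfinite(vals)
    if ok.sum() < 25:
        raise ValueError("need at least a 5x5 grid of valid offsets")
    if np.nanmax(vals) - np.nanmin(vals) < 1e-12:
        raise ValueError("constant difference map: ellipse undefined")
    s = np.nanmax(vals) - vals
    cell = diff_map.pixel_scale ** 2
    s = s / (np.nansum(s) * cell)   # unit volume

    X, Y = np.meshgrid(diff_map.offsets_x, diff_map.offsets_y)
    x, y, z = X[ok], Y[ok], s[ok]

    # moment-based initialization
    w = np.maximum(z, 0)
    wsum = w.sum()
    sxx = float((w * x * x).sum() / wsum)
    syy = float((w * y * y).sum() / wsum)
    sxy = float((w * x * y).sum() / wsum)

    def unpack(p):
        l11, l21, l22, loga = p
        L = np.array([[l11, 0.0], [l21, l22]])
        return L @ L.T, np.exp(loga)

    def resid(p):
        cov, amp = unpack(p)
        inv = np.linalg.inv(cov)
        q = inv[0, 0] * x * x + 2 * inv[0, 1] * x * y + inv[1, 1] * y * y
        return amp * np.exp(-0.5 * q) - z

    init_cov = np.array([[max(sxx, 1e-3), sxy], [sxy, max(syy, 1e-3)]])
    try:
        L0 = np.linalg.cholesky(init_cov)
    except np.linalg.LinAlgError:
        L0 = np.linalg.cholesky(np.diag(np.diag(init_cov)))
    p0 = [L0[0, 0], L0[1, 0], L0[1, 1], np.log(max(z.max(), 1e-9))]
    sol = least_squares(resid, p0, method="lm", max_nfev=2000)
    cov, _ = unpack(sol.x)
    if np.linalg.det(cov) <= 0 or cov[0, 0] <= 0:
        raise ValueError("fitted covariance is not positive definite")
    return EllipseFit.from_covariance(cov, condition=diff_map.condition)


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the same area: ``D = 2 sqrt(A/pi)``."""
    return float(2.0 * np.sqrt(area / np.pi))


def _orientation_from_rule(rule, bin_center_tilt, fit: EllipseFit):
    if callable(rule):
        return float(rule(bin_center_tilt)) % 180.0
    if rule == "orthogonal":
        return (bin_center_tilt + 90.0) % 180.0
    if rule == "aligned":
        return bin_center_tilt % 180.0
    if rule == "fitted":
        return fit.orientation
    raise ValueError(f"unknown orientation rule {rule!r}")


def pooling_spec_from_stats(fits, orientation_rule="orthogonal",
                            n_bins: int = 24) -> PoolingSpec:
    """Build a :class:`PoolingSpec` from per-tilt-bin ellipse fits.

    ``fits`` maps bin index -> :class:`EllipseFit`; every bin must be
    present.  Relative areas are normalized to mean 1; the average
    equivalent diameter is computed from the arithmetic mean area across
    bins.  The orientation rule maps the bin-centre tilt to the pooling
    ellipse orientation ("orthogonal" elongation by default, "aligned",
    "fitted", or any callable).
    """
    missing = [b for b in range(n_bins) if b not in fits]
    if missing:
        raise ValueError(f"missing ellipse fits for bins {missing}")
    centers = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    areas = np.array([fits[b].area for b in range(n_bins)])
    aspect = np.array([fits[b].aspect_ratio for b in range(n_bins)])
    orient = np.array([_orientation_from_rule(orientation_rule, centers[b], fits[b])
                       for b in range(n_bins)])
    mean_area = float(areas.mean())
    return PoolingSpec(n_bins=n_bins,
                       relative_area=areas / mean_area,
                       aspect_ratio=aspect,
                       orientation=orient,
                       fitted_dbar=equivalent_diameter(mean_area))
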