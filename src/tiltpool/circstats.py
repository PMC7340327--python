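"""Circular (angular) arithmetic for tilt variables.

Surface tilt is a circular variable: signed tilt lives on [0, 360) degrees,
unsigned tilt (and image-cue orientations) on [0, 180).  Every downstream
computation -- conditional means in the lookup tables, spatial pooling,
tilt-difference maps, error metrics -- reduces to the primitives here:
circular differences and resultant-vector (phasor) means.

Two conventions coexist for means of axial (period-180) data.  The standard
estimator doubles the angle before phasor summation; the convention used
throughout this package's lookup tables instead sums phasors at the raw
angle on the full circle and reduces the resulting mean modulo 180.  Both
are available; see :func:`circ_mean` and the ``angle_doubling`` switches in
:mod:`tiltpool.lut`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateResultantError",
    "ResultantSummary",
    "wrap_angle",
    "signed_diff",
    "abs_diff",
    "resultant",
    "circ_mean",
    "circ_variance",
    "mean_abs_diff",
]


def wrap_angle(angle, period: float = 360.0):
    """Reduce angles to ``[0, period)``, guarding the floating-point case
    where the modulo of a tiny negative angle rounds to ``period`` itself."""
    a = np.mod(angle, period)
    a = np.where(a >= period, 0.0, a)
    if np.ndim(angle) == 0:
        return float(a)
    return a

#: tolerance on resultant length (as a fraction of total weight) below which
#: the circular mean is treated as undefined
DEGENERATE_TOL = 1e-9

_VALID_PERIODS = (180.0, 360.0)


class DegenerateResultantError(ValueError):
    """Raised when the resultant vector is too short to define a mean."""


def _check_period(period: float) -> float:
    period = float(period)
    if period not in _VALID_PERIODS:
        raise ValueError(f"period must be 180 or 360 degrees, got {period}")
    return period


def signed_diff(a, b, period: float = 360.0):
    """Signed circular difference ``a - b`` in ``(-period/2, period/2]``.

    Antipodal pairs (difference of exactly half a period) map to
    ``+period/2``, so the sign convention is deterministic.
    """
    period = _check_period(period)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("signed_diff requires finite inputs")
    d = np.mod(a - b, period)
    out = np.where(d > period / 2.0, d - period, d)
    if out.ndim == 0:
        return float(out)
    return out


def abs_diff(a, b, period: float = 360.0):
    """Absolute circular distance in ``[0, period/2]`` (Fig. 2 metric)."""
    return np.abs(signed_diff(a, b, period))


@dataclass(frozen=True)
class ResultantSummary:
    """Mean direction and resultant length of a set of weighted angles."""

    mean_angle: float
    resultant_length: float
    n: int
    weight_total: float
    period: float = 360.0


def resultant(angles, weights=None, period: float = 360.0):
    """Weighted phasor sum ``sum w_k exp(j angle_k * 360/period)``.

    Returns ``(z, weight_total, n)``.  Angles are scaled to the full circle
    before summation, so the period-180 case is the standard axial
    (angle-doubled) embedding.
    """
    period = _check_period(period)
    angles = np.asarray(angles, dtype=float).ravel()
    if angles.size < 1:
        raise ValueError("need at least one angle")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    if weights is None:
        w = np.ones_like(angles)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != angles.shape:
            raise ValueError("weights must match angles in length")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and non-negative")
    wtot = float(w.sum())
    if wtot <= 0:
        raise ValueError("weights must not all be zero")
    scale = 360.0 / period
    z = complex(np.sum(w * np.exp(1j * np.deg2rad(angles * scale))))
    return z, wtot, int(angles.size)


def circ_mean(angles, weights=None, period: float = 360.0,
              tol: float = DEGENERATE_TOL) -> ResultantSummary:
    """Weighted circular mean via the resultant vector.

    The mean is ``arg(sum w_k e^{j angle_k 360/period}) * period/360``
    reduced to ``[0, period)``.  A resultant shorter than ``tol`` times the
    total weight means the mean direction is undefined (e.g. two equal
    weights at antipodes) and raises :class:`DegenerateResultantError`.
    """
    period = _check_period(period)
    z, wtot, n = resultant(angles, weights, period)
    r = abs(z) / wtot
    if r < tol:
        raise DegenerateResultantError(
            f"resultant length {r:.3e} below tolerance {tol:.1e}: "
            "circular mean undefined")
    scale = 360.0 / period
    mean = wrap_angle(np.rad2deg(np.angle(z)) / scale, period)
    return ResultantSummary(mean_angle=float(mean), resultant_length=float(r),
                            n=n, weight_total=wtot, period=period)


def circ_variance(angles, weights=None, period: float = 360.0) -> float:
    """Circular variance ``1 - R`` in [0, 1]; 0 for identical angles."""
    z, wtot, _ = resultant(angles, weights, period)
    return float(1.0 - abs(z) / wtot)


def phasor_mean_angle(z, period: float = 360.0) -> float:
    """Mean angle of an accumulated phasor, reduced to ``[0, period)``.

    Used by the lookup tables, which accumulate raw (undoubled) phasors of
    unsigned tilt on the full circle and reduce the mean modulo 180.
    """
    _check_period(period)
    return float(wrap_angle(np.rad2deg(np.angle(z)), period))


def mean_abs_diff(estimates, references, period: float = 360.0,
                  aggregation: str = "circular") -> float:
    """Mean absolute circular distance across pairs of tilts.

    ``aggregation="circular"`` follows the definition used for the
    tilt-difference maps: the set of absolute distances ``|Δτ| ∈ [0, 180]``
    is itself averaged as a circular quantity, ``arg(Σ_k e^{j|Δτ_k|})``
    reduced to ``[0, 360)``.  ``aggregation="arithmetic"`` takes the plain
    arithmetic mean of the absolute distances.  Both are exposed because the
    two differ for widely dispersed differences.
    """
    d = abs_diff(estimates, references, period)
    d = np.atleast_1d(d)
    if d.size < 1:
        raise ValueError("need at least one pair")
    if aggregation == "arithmetic":
        return float(np.mean(d))
    if aggregation != "circular":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    summary = circ_mean(d, period=360.0)
    return summary.mean_angle
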