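"""Stage 1: the local Bayesian tilt estimator backed by lookup tables.

Training accumulates, for every pixel where all cues and groundtruth tilt
are defined, a unit phasor of the groundtruth tilt *magnitude* into the
cell indexed by the quantized unsigned cue triplet (luminance, texture,
disparity; 64^3 cells), and a unit phasor of the *signed* groundtruth tilt
into the cell indexed by the quantized signed disparity cue (64 cells).

Tilt magnitude is the absolute value of signed tilt centred on (-180, 180]:
it is the decomposition of signed tilt into magnitude x sign, so the
product of the magnitude estimate and the sign estimate reconstructs
signed tilt (magnitude 120 with sign -1 is -120, i.e. 240 degrees).

At test time the magnitude estimate is the stored conditional circular
mean for the cue triplet (the posterior mean under a minimum-circular-
distance cost), the tilt sign is the sign of the conditional mean of
signed tilt given the signed disparity cue, and the signed local estimate
is their product.  By default magnitude means follow the raw-phasor
convention (sum of e^{j tau_u}, mean direction folded back onto [0, 180]);
``angle_doubling=True`` switches to the standard axial estimator.
Accumulation is an exact commutative merge: training on a union of scenes
equals summing tables trained on the parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cues import N_CUE_BINS, QuantizedCues
from .geometry import TiltMap

__all__ = ["LookupTables", "LocalEstimateMap", "train_luts", "estimate_local",
           "area_matched_sigma"]

logger = logging.getLogger(__name__)

#: provenance codes for estimate_local
PROV_CELL = 0          # full cue-triplet cell
PROV_DU_MARGINAL = 1   # fallback: disparity-cue marginal
PROV_PRIOR = 2         # fallback: global prior mean


@dataclass
class LocalEstimateMap:
    """Signed local tilt estimates in [0, 360) with validity and provenance."""

    tilt_estimate: np.ndarray
    defined_mask: np.ndarray
    provenance: np.ndarray = None


class LookupTables:
    """Phasor/count accumulators for the conditional-mean lookup tables."""

    def __init__(self, n_bins: int = N_CUE_BINS, angle_doubling: bool = False):
        self.n_bins = int(n_bins)
        self.angle_doubling = bool(angle_doubling)
        n = self.n_bins
        self.unsigned_phasor = np.zeros((n, n, n), dtype=np.complex128)
        self.unsigned_count = np.zeros((n, n, n), dtype=np.int64)
        self.sign_phasor = np.zeros(n, dtype=np.complex128)
        self.sign_count = np.zeros(n, dtype=np.int64)
        self.du_marginal_phasor = np.zeros(n, dtype=np.complex128)
        self.du_marginal_count = np.zeros(n, dtype=np.int64)
        self.prior_phasor = 0.0 + 0.0j
        self.prior_count = 0

    # -- training ----------------------------------------------------------

    def _unsigned_phase(self, tilt_magnitude_deg):
        mult = 2.0 if self.angle_doubling else 1.0
        return np.exp(1j * np.deg2rad(mult * tilt_magnitude_deg))

    def accumulate(self, qcues: QuantizedCues, tilt: TiltMap):
        """Accumulate one scene's pixels into the tables.

        Tilt *magnitude* (the absolute value of signed tilt centred on
        (-180, 180]) feeds the unsigned tables: it is the quantity whose
        product with the estimated sign reconstructs signed tilt.  Per-scene
        contributions are pre-summed so that accumulation is an exact
        commutative merge.
        """
        from .circstats import signed_diff
        mask = qcues.defined_mask & tilt.defined_mask
        if not np.any(mask):
            return 0
        ts = tilt.tilt_signed[mask]
        tu = np.abs(signed_diff(ts, 0.0, 360.0))   # magnitude in [0, 180]
        zu = self._unsigned_phase(tu)
        zs = np.exp(1j * np.deg2rad(ts))
        flat = np.ravel_multi_index(
            (qcues.lum_u[mask], qcues.tex_u[mask], qcues.disp_u[mask]),
            self.unsigned_phasor.shape)
        n_flat = self.unsigned_phasor.size
        self.unsigned_phasor += np.bincount(
            flat, weights=zu.real, minlength=n_flat).reshape(
                self.unsigned_phasor.shape) + 1j * np.bincount(
                    flat, weights=zu.imag, minlength=n_flat).reshape(
                        self.unsigned_phasor.shape)
        self.unsigned_count += np.bincount(
            flat, minlength=n_flat).reshape(self.unsigned_count.shape)
        nb = self.n_bins
        self.sign_phasor += (np.bincount(qcues.disp_s[mask], weights=zs.real,
                                         minlength=nb)
                             + 1j * np.bincount(qcues.disp_s[mask],
                                                weights=zs.imag, minlength=nb))
        self.sign_count += np.bincount(qcues.disp_s[mask], minlength=nb)
        self.du_marginal_phasor += (
            np.bincount(qcues.disp_u[mask], weights=zu.real, minlength=nb)
            + 1j * np.bincount(qcues.disp_u[mask], weights=zu.imag,
                               minlength=nb))
        self.du_marginal_count += np.bincount(qcues.disp_u[mask], minlength=nb)
        self.prior_phasor += zu.sum()
        self.prior_count += int(mask.sum())
        return int(mask.sum())

    def merge(self, other: "LookupTables") -> "LookupTables":
        """Exact table merge (phasor and count addition)."""
        if (other.n_bins != self.n_bins
                or other.angle_doubling != self.angle_doubling):
            raise ValueError("incompatible lookup tables")
        out = LookupTables(self.n_bins, self.angle_doubling)
        for name in ("unsigned_phasor", "unsigned_count", "sign_phasor",
                     "sign_count", "du_marginal_phasor", "du_marginal_count"):
            setattr(out, name, getattr(self, name) + getattr(other, name))
        out.prior_phasor = self.prior_phasor + other.prior_phasor
        out.prior_count = self.prior_count + other.prior_count
        return out

    __add__ = merge

    # -- derived quantities -------------------------------------------------

    def _phasor_to_unsigned_mean(self, z):
        from .circstats import wrap_angle
        ang = np.rad2deg(np.angle(z))   # (-180, 180]
        if self.angle_doubling:
            return wrap_angle(ang / 2.0, 180.0)
        # magnitudes live on [0, 180]; fold the mean direction back onto it
        return np.abs(ang)

    def unsigned_means(self):
        """Conditional mean unsigned tilt per cue-triplet cell; NaN if empty."""
        with np.errstate(invalid="ignore"):
            means = self._phasor_to_unsigned_mean(self.unsigned_phasor)
        return np.where(self.unsigned_count > 0, means, np.nan)

    def sign_means(self):
        """+1/-1 per signed-disparity-cue cell; +1 on zero resultant; NaN empty."""
        ang = np.rad2deg(np.angle(self.sign_phasor))  # (-180, 180]
        degenerate = (np.abs(self.sign_phasor)
                      < 1e-9 * np.maximum(self.sign_count, 1))
        if np.any(degenerate & (self.sign_count > 0)):
            logger.warning("zero-resultant sign cell(s): defaulting to +1")
        sign = np.where(ang >= 0.0, 1.0, -1.0)
        sign = np.where(degenerate, 1.0, sign)
        return np.where(self.sign_count > 0, sign, np.nan)

    def prior_mean(self):
        """Circular mean unsigned tilt over all training pixels."""
        if self.prior_count == 0:
            raise ValueError("no training data")
        return float(self._phasor_to_unsigned_mean(self.prior_phasor))

    # -- persistence ---------------------------------------------------------

    def save(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["n_bins"] = self.n_bins
            f.attrs["angle_doubling"] = self.angle_doubling
            f.attrs["prior_phasor_real"] = self.prior_phasor.real
            f.attrs["prior_phasor_imag"] = self.prior_phasor.imag
            f.attrs["prior_count"] = self.prior_count
            for name in ("unsigned_phasor", "sign_phasor", "du_marginal_phasor"):
                arr = getattr(self, name)
                f.create_dataset(name + "_real", data=arr.real)
                f.create_dataset(name + "_imag", data=arr.imag)
            for name in ("unsigned_count", "sign_count", "du_marginal_count"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load(cls, path) -> "LookupTables":
        import h5py
        with h5py.File(path, "r") as f:
            luts = cls(int(f.attrs["n_bins"]), bool(f.attrs["angle_doubling"]))
            luts.prior_phasor = complex(f.attrs["prior_phasor_real"],
                                        f.attrs["prior_phasor_imag"])
            luts.prior_count = int(f.attrs["prior_count"])
            for name in ("unsigned_phasor", "sign_phasor", "du_marginal_phasor"):
                setattr(luts, name, f[name + "_real"][...]
                        + 1j * f[name + "_imag"][...])
            for name in ("unsigned_count", "sign_count", "du_marginal_count"):
                setattr(luts, name, f[name][...])
        return luts


def train_luts(training_pairs, n_bins: int = N_CUE_BINS,
               angle_doubling: bool = False) -> LookupTables:
    """Train lookup tables from ``(QuantizedCues, TiltMap)`` pairs."""
    luts = LookupTables(n_bins, angle_doubling)
    total = 0
    for qcues, tilt in training_pairs:
        total += luts.accumulate(qcues, tilt)
    if total == 0:
        raise ValueError("no defined training pixels")
    return luts


def estimate_local(qcues: QuantizedCues, luts: LookupTables) -> LocalEstimateMap:
    """Signed local tilt estimate per pixel from the trained tables.

    Pixels whose cue triplet hits an empty cell back off to the conditional
    mean given the unsigned disparity cue alone, then to the global prior
    mean; the provenance array records which path produced each estimate.
    """
    if qcues.n_bins != luts.n_bins:
        raise ValueError("cue quantization does not match table binning")
    shape = qcues.lum_u.shape
    flat_idx = np.ravel_multi_index(
        (qcues.lum_u, qcues.tex_u, qcues.disp_u), luts.unsigned_phasor.shape)
    cell_means = luts.unsigned_means().reshape(-1)[flat_idx]
    provenance = np.full(shape, PROV_CELL, dtype=np.int8)

    du_means = np.where(
        luts.du_marginal_count > 0,
        luts._phasor_to_unsigned_mean(luts.du_marginal_phasor), np.nan)
    du_fallback = du_means[qcues.disp_u]
    need = np.isnan(cell_means)
    provenance[need] = PROV_DU_MARGINAL
    est_u = np.where(need, du_fallback, cell_means)
    still = np.isnan(est_u)
    provenance[still] = PROV_PRIOR
    est_u = np.where(still, luts.prior_mean(), est_u)

    signs = luts.sign_means()[qcues.disp_s]
    signs = np.where(np.isnan(signs), 1.0, signs)
    est = np.where(signs > 0, est_u, np.mod(-est_u, 360.0)) % 360.0
    return LocalEstimateMap(tilt_estimate=est,
                            defined_mask=qcues.defined_mask.copy(),
                            provenance=provenance)


def area_matched_sigma(diameter_deg: float = 1.0) -> float:
    """Cue space constant (arcmin) whose truncated support diameter
    (two kernel truncation radii, i.e. six space constants) matches a target
    visual angle -- the area-matched single-stage control model."""
    return diameter_deg * 60.0 / 6.0
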