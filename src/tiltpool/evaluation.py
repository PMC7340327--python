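"""Evaluation: error metrics, pooling-diameter sweeps, diagnostics.

*Estimation error* is the absolute circular distance between a model
estimate and groundtruth tilt; *prediction error* the distance between a
model estimate and a human (or simulated) estimate.  Errors are aggregated
either as the circular mean of the absolute distances (consistent with the
tilt-difference-map statistic; the default) or as the plain arithmetic
mean.

Sweeps evaluate the global model across pooling diameters on a stimulus
ensemble; the zero-diameter entry reproduces the local model exactly.
Bootstrap resampling of stimuli gives confidence intervals; per-tilt-bin
argmin diameters can be correlated (Pearson, permutation p-value) against
the diameters predicted by the scene-statistics fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import DegenerateResultantError, abs_diff, circ_mean, mean_abs_diff
from .geometry import ViewingGeometry
from .lut import LocalEstimateMap
from .pooling import estimate_global
from .statistics import PoolingSpec

__all__ = [
    "SceneStimuli",
    "ErrorCurve",
    "mean_error",
    "per_target_errors",
    "sweep_diameters",
    "bootstrap_ci",
    "best_diameter_per_tilt",
    "diameter_correlation",
    "reliability_diagnostic",
    "consensus_baseline",
]


@dataclass
class SceneStimuli:
    """Target locations within one scene's local-estimate map.

    ``references`` are the per-target reference tilts (groundtruth for
    estimation error, human/observer responses for prediction error);
    ``keys`` are the tilts the adaptive region is keyed on (defaults to the
    references).
    """

    local_map: LocalEstimateMap
    geometry: ViewingGeometry
    targets: np.ndarray           # (N, 2) ints (row, col)
    references: np.ndarray        # (N,) degrees
    keys: np.ndarray = None
    groundtruth_map: np.ndarray = None

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=int)
        self.references = np.asarray(self.references, dtype=float)
        if self.keys is None:
            self.keys = self.references.copy()


@dataclass
class ErrorCurve:
    """Mean error vs. pooling diameter, with optional CI bounds."""

    diameters: np.ndarray
    mean_error: np.ndarray
    ci_low: np.ndarray = None
    ci_high: np.ndarray = None
    kind: str = "estimation"
    model: str = "fixed"
    per_target: np.ndarray = None   # (n_targets, n_diameters)

    def __post_init__(self):
        d = np.asarray(self.diameters, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly increasing")


def mean_error(estimates, references, aggregation: str = "circular") -> float:
    """Mean absolute circular error (degrees) between matched tilt lists."""
    est = np.atleast_1d(np.asarray(estimates, dtype=float))
    ref = np.atleast_1d(np.asarray(references, dtype=float))
    if est.size == 0:
        raise ValueError("empty estimate table")
    if est.shape != ref.shape:
        raise ValueError("estimates and references must be matched")
    return mean_abs_diff(est, ref, period=360.0, aggregation=aggregation)


def _key_map_for(stim: SceneStimuli):
    if stim.groundtruth_map is not None:
        return stim.groundtruth_map
    key_map = np.zeros(stim.local_map.tilt_estimate.shape)
    key_map[stim.targets[:, 0], stim.targets[:, 1]] = stim.keys
    return key_map


def per_target_errors(stimuli, diameter_arcmin: float, mode: str = "fixed",
                      spec: PoolingSpec = None, key_mode: str = "groundtruth",
                      weights: str = "uniform"):
    """Absolute circular error per target at one pooling diameter.

    ``stimuli`` is a list of :class:`SceneStimuli`; returns the
    concatenated per-target error vector (NaN where the estimate is
    undefined) and the matching reference-tilt vector.
    """
    errs, refs = [], []
    for stim in stimuli:
        est = estimate_global(stim.local_map, stim.geometry, mode=mode,
                              diameter_arcmin=diameter_arcmin, spec=spec,
                              key_mode=key_mode, key_tilt=_key_map_for(stim),
                              targets=stim.targets, weights=weights)
        ok = np.isfinite(est)
        e = np.full(len(est), np.nan)
        e[ok] = abs_diff(est[ok], stim.references[ok], 360.0)
        errs.append(e)
        refs.append(stim.references)
    return np.concatenate(errs), np.concatenate(refs)


def sweep_diameters(stimuli, diameters, mode: str = "fixed",
                    spec: PoolingSpec = None, key_mode: str = "groundtruth",
                    aggregation: str = "circular",
                    kind: str = "estimation") -> ErrorCurve:
    """Mean error as a function of pooling diameter (arcmin).

    A diameter of zero pools over the single target pixel and therefore
    reproduces the local model's error exactly.
    """
    diameters = np.asarray(diameters, dtype=float)
    if diameters.size < 1:
        raise ValueError("need at least one diameter")
    per = []
    means = []
    for d in diameters:
        e, _ = per_target_errors(stimuli, d, mode=mode, spec=spec,
                                 key_mode=key_mode)
        per.append(e)
        ok = np.isfinite(e)
        means.append(mean_abs_diff(e[ok], np.zeros(ok.sum()),
                                   aggregation=aggregation))
    return ErrorCurve(diameters=diameters, mean_error=np.asarray(means),
                      kind=kind, model=mode, per_target=np.column_stack(per))


def bootstrap_ci(per_stimulus_errors, n_sets: int = 1000, seed: int = 0,
                 aggregation: str = "circular", level: float = 0.95):
    """Percentile bootstrap CI of the mean error over stimulus resamples."""
    errs = np.asarray(per_stimulus_errors, dtype=float)
    errs = errs[np.isfinite(errs)]
    if errs.size < 2:
        raise ValueError("need at least two stimuli")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, errs.size, size=(n_sets, errs.size))
    if aggregation == "arithmetic":
        stats = errs[idx].mean(axis=1)
    else:
        z = np.exp(1j * np.deg2rad(errs))
        stats = np.rad2deg(np.angle(z[idx].sum(axis=1))) % 360.0
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def best_diameter_per_tilt(stimuli, diameters, n_bins: int = 24,
                           mode: str = "adaptive", spec: PoolingSpec = None,
                           key_mode: str = "groundtruth",
                           aggregation: str = "circular") -> pd.DataFrame:
    """Argmin pooling diameter per target-tilt bin (ties -> smallest).

    Returns a frame (bin, best_diameter, n_targets, min_error); raises if
    any bin has no targets.
    """
    curve = sweep_diameters(stimuli, diameters, mode=mode, spec=spec,
                            key_mode=key_mode, aggregation=aggregation)
    refs = np.concatenate([s.references for s in stimuli])
    bins = (np.floor(np.mod(refs, 360.0) * n_bins / 360.0).astype(int)
            % n_bins)
    recs = []
    for b in range(n_bins):
        sel = bins == b
        if not np.any(sel):
            raise ValueError(f"tilt bin {b} has no targets")
        errs_b = curve.per_target[sel]
        means = []
        for k in range(len(diameters)):
            e = errs_b[:, k]
            e = e[np.isfinite(e)]
            means.append(mean_abs_diff(e, np.zeros(e.size),
                                       aggregation=aggregation))
        means = np.asarray(means)
        # ties (to numerical precision) resolve to the smallest diameter
        best = int(np.flatnonzero(means <= means.min() + 1e-9)[0])
        recs.append(dict(bin=b, best_diameter=float(diameters[best]),
                         n_targets=int(sel.sum()),
                         min_error=float(means[best])))
    return pd.DataFrame(recs)


def diameter_correlation(best_diameters, predicted_diameters,
                         n_perm: int = 10_000, seed: int = 0):
    """Pearson correlation between per-bin best diameters and the diameters
    predicted by the scene-statistics fits, with a permutation p-value.

    Returns ``(r, p)``; ``(nan, nan)`` when either vector is constant
    (correlation undefined -- flagged, not asserted).
    """
    a = np.asarray(best_diameters, dtype=float)
    b = np.asarray(predicted_diameters, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    perm_r = np.empty(n_perm)
    for i in range(n_perm):
        perm_r[i] = np.corrcoef(a, rng.permutation(b))[0, 1]
    p = float((np.sum(np.abs(perm_r) >= abs(r)) + 1) / (n_perm + 1))
    return r, p


def reliability_diagnostic(estimates, groundtruth, n_estimate_bins: int = 12,
                           n_gt_bins: int = 24):
    """Conditional distributions of groundtruth tilt given the estimate.

    Returns ``(table, shift_invariance_score)`` where ``table[k]`` is the
    normalized histogram of groundtruth tilt for estimates in bin ``k``,
    and the score is the mean pairwise total-variation distance between the
    conditionals after recentring each on its estimate bin (reported, not
    asserted: small scores mean the estimate is an equally reliable
    predictor of groundtruth regardless of its value).
    """
    est = np.asarray(estimates, dtype=float).ravel()
    gt = np.asarray(groundtruth, dtype=float).ravel()
    ebins = (np.floor(np.mod(est, 360.0) * n_estimate_bins / 360.0)
             .astype(int) % n_estimate_bins)
    table = np.zeros((n_estimate_bins, n_gt_bins))
    recentred = np.zeros_like(table)
    for k in range(n_estimate_bins):
        sel = ebins == k
        if not np.any(sel):
            table[k] = np.nan
            recentred[k] = np.nan
            continue
        center = (k + 0.5) * 360.0 / n_estimate_bins
        h = np.histogram(np.mod(gt[sel], 360.0),
                         bins=np.linspace(0, 360, n_gt_bins + 1))[0]
        table[k] = h / h.sum()
        shifted = np.mod(gt[sel] - center + 180.0, 360.0)
        hs = np.histogram(shifted, bins=np.linspace(0, 360, n_gt_bins + 1))[0]
        recentred[k] = hs / hs.sum()
    ok = ~np.isnan(recentred).any(axis=1)
    score = np.nan
    if ok.sum() >= 2:
        rs = recentred[ok]
        dists = [0.5 * np.abs(rs[i] - rs[j]).sum()
                 for i in range(len(rs)) for j in range(i + 1, len(rs))]
        score = float(np.mean(dists))
    return table, score


def consensus_baseline(responses: pd.DataFrame):
    """Per-stimulus circular mean of multiple observers' estimates.

    ``responses`` needs columns ``stimulus``, ``observer``, ``estimate``.
    Returns a frame (stimulus, consensus, n_observers, degenerate); the
    consensus is NaN and flagged where the observers' resultant collapses.
    """
    req = {"stimulus", "observer", "estimate"}
    if not req.issubset(responses.columns):
        raise ValueError(f"response table needs columns {sorted(req)}")
    recs = []
    for stim, grp in responses.groupby("stimulus"):
        if grp["observer"].nunique() < 2:
            raise ValueError(f"stimulus {stim!r} has fewer than 2 observers")
        try:
            summary = circ_mean(grp["estimate"].to_numpy(), period=360.0)
            recs.append(dict(stimulus=stim, consensus=summary.mean_angle,
                             n_observers=int(grp["observer"].nunique()),
                             degenerate=False))
        except DegenerateResultantError:
            recs.append(dict(stimulus=stim, consensus=np.nan,
                             n_observers=int(grp["observer"].nunique()),
                             degenerate=True))
    return pd.DataFrame(recs)
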