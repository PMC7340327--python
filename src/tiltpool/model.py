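"""Model-level interface: fit the full hierarchy to a scene ensemble.

:class:`HierarchicalTiltModel` bundles the whole estimation hierarchy the
way a statistical modelling package would: it is constructed from data (a
list of scenes with groundtruth, or pre-computed cue/tilt pairs), ``fit()``
trains the cue lookup tables and fits the elliptical pooling spec to the
ensemble's tilt statistics, and the returned
:class:`HierarchicalTiltResults` carries the fitted tables, the pooling
specification, occupancy diagnostics, ``estimate()`` for new scenes and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cues import compute_cue_maps, quantize_cues
from .geometry import RangeScene, TiltMap, ViewingGeometry, tilt_from_range
from .lut import LookupTables, LocalEstimateMap, estimate_local, train_luts
from .pooling import estimate_global
from .statistics import (PoolingSpec, fit_pooling_ellipse, mean_diff_map,
                         pooling_spec_from_stats, tilt_prior_histogram)

__all__ = ["HierarchicalTiltModel", "HierarchicalTiltResults"]


class HierarchicalTiltModel:
    """Two-stage tilt estimator fitted to a scene ensemble.

    Parameters
    ----------
    scenes : list of (RangeScene, TiltMap) or RangeScene
        Training ensemble; tilt maps are derived from the range maps when
        not supplied.
    sigma_tilt, sigma_cue : float
        Space constants (arcmin) of the groundtruth-tilt and cue operators.
    n_cue_bins : int
        Quantization levels per cue (default 64).
    n_tilt_bins : int
        Conditioning bins for the per-tilt statistics (default 24 x 15 deg).
    max_offset_arcmin : float
        Spatial extent of the tilt-difference maps used for the ellipse fits.
    orientation_rule : str or callable
        Pooling-ellipse orientation as a function of target tilt
        ("orthogonal" by default).
    angle_doubling : bool
        Use the axial (angle-doubled) estimator for unsigned means.
    use_groundtruth_disparity : bool
        Bypass stereo matching with the scene's true disparity map.
    """

    def __init__(self, scenes, sigma_tilt: float = 3.0, sigma_cue: float = 6.0,
                 n_cue_bins: int = 64, n_tilt_bins: int = 24,
                 max_offset_arcmin: float = 12.0,
                 orientation_rule="orthogonal", angle_doubling: bool = False,
                 use_groundtruth_disparity: bool = False):
        self.pairs = []
        for item in scenes:
            if isinstance(item, RangeScene):
                self.pairs.append((item, tilt_from_range(item, sigma_tilt)))
            else:
                self.pairs.append(tuple(item))
        if not self.pairs:
            raise ValueError("need at least one training scene")
        self.geometry = self.pairs[0][0].geometry
        self.sigma_tilt = sigma_tilt
        self.sigma_cue = sigma_cue
        self.n_cue_bins = n_cue_bins
        self.n_tilt_bins = n_tilt_bins
        self.max_offset_arcmin = max_offset_arcmin
        self.orientation_rule = orientation_rule
        self.angle_doubling = angle_doubling
        self.use_groundtruth_disparity = use_groundtruth_disparity

    def _cues_for(self, scene: RangeScene):
        gt_disp = None
        if self.use_groundtruth_disparity:
            from .geometry import disparity_from_range
            gt_disp = disparity_from_range(scene)
        return compute_cue_maps(scene, sigma_cue=self.sigma_cue,
                                disparity_groundtruth=gt_disp)

    def fit(self) -> "HierarchicalTiltResults":
        training = []
        tilt_maps = []
        for scene, tilt in self.pairs:
            qc = quantize_cues(self._cues_for(scene), self.n_cue_bins)
            training.append((qc, tilt))
            tilt_maps.append(tilt)
        luts = train_luts(training, self.n_cue_bins, self.angle_doubling)

        fits = {}
        for b in range(self.n_tilt_bins):
            dm = mean_diff_map(tilt_maps, self.max_offset_arcmin,
                               pixel_scale=self.geometry.pixel_scale,
                               condition_bin=b, n_bins=self.n_tilt_bins)
            fits[b] = fit_pooling_ellipse(dm)
        spec = pooling_spec_from_stats(fits, self.orientation_rule,
                                       self.n_tilt_bins)
        prior = tilt_prior_histogram(tilt_maps, self.n_tilt_bins)
        return HierarchicalTiltResults(model=self, luts=luts, pooling_spec=spec,
                                       ellipse_fits=fits, tilt_prior=prior)


@dataclass
class HierarchicalTiltResults:
    """Fitted lookup tables, pooling spec and diagnostics."""

    model: HierarchicalTiltModel
    luts: LookupTables
    pooling_spec: PoolingSpec
    ellipse_fits: dict
    tilt_prior: np.ndarray

    def estimate_local(self, scene: RangeScene) -> LocalEstimateMap:
        qc = quantize_cues(self.model._cues_for(scene), self.model.n_cue_bins)
        return estimate_local(qc, self.luts)

    def estimate(self, scene: RangeScene, mode: str = "adaptive",
                 diameter_arcmin: float = None, key_mode: str = "local_estimate",
                 groundtruth_tilt=None, targets=None):
        """Global tilt estimates for a scene at the fitted (or given)
        pooling diameter."""
        if diameter_arcmin is None:
            diameter_arcmin = self.pooling_spec.fitted_dbar
        local = self.estimate_local(scene)
        key_tilt = groundtruth_tilt
        if key_mode == "groundtruth" and key_tilt is None:
            key_tilt = tilt_from_range(scene, self.model.sigma_tilt).tilt_signed
        return estimate_global(local, scene.geometry, mode=mode,
                               diameter_arcmin=diameter_arcmin,
                               spec=self.pooling_spec, key_mode=key_mode,
                               key_tilt=key_tilt, targets=targets)

    def summary(self) -> str:
        luts = self.luts
        occ = float((luts.unsigned_count > 0).mean())
        n_train = int(luts.prior_count)
        spec = self.pooling_spec
        lines = [
            "Hierarchical surface-tilt model",
            "=" * 46,
            f"training pixels            {n_train:>12,d}",
            f"cue bins per dimension     {luts.n_bins:>12d}",
            f"occupied cue-triplet cells {occ:>12.1%}",
            f"unsigned-mean convention   {'doubled' if luts.angle_doubling else 'raw phasor':>12s}",
            f"tilt bins (statistics)     {spec.n_bins:>12d}",
            f"fitted average eq. diam    {spec.fitted_dbar:>9.1f} arcmin",
            f"aspect ratio (min..max)    "
            f"{spec.aspect_ratio.min():>6.2f} .. {spec.aspect_ratio.max():.2f}",
            f"relative area (min..max)   "
            f"{spec.relative_area.min():>6.2f} .. {spec.relative_area.max():.2f}",
            f"cardinal-bin prior mass    "
            f"{self._cardinal_mass():>12.1%}",
        ]
        return "\n".join(lines)

    def _cardinal_mass(self):
        n = self.model.n_tilt_bins
        width = 360.0 / n
        bins = [int(c // width) % n for c in (0, 90, 180, 270)]
        return float(np.sum(self.tilt_prior[bins]))
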