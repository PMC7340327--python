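import numpy as np
import pandas as pd
import pytest

from helpers import weighted_phasor_mean
from tiltpool.circstats import abs_diff
from tiltpool.evaluation import (SceneStimuli, best_diameter_per_tilt,
                                 bootstrap_ci, consensus_baseline,
                                 diameter_correlation, mean_error,
                                 per_target_errors, reliability_diagnostic,
                                 sweep_diameters)
from tiltpool.geometry import ViewingGeometry
from tiltpool.lut import LocalEstimateMap
from tiltpool.synthetic import (generate_patchwork_tilt_map,
                                noisy_local_estimates)


@pytest.fixture
def geom():
    return ViewingGeometry(pixel_scale=1.0, fixation_distance_m=10.0,
                           image_size=(96, 96))


def _stimuli(tilt_map, noise_sd, seed, n_targets=150, margin=12,
             geom=None):
    est = noisy_local_estimates(tilt_map, noise_sd, seed=seed)
    lm = LocalEstimateMap(tilt_estimate=est,
                          defined_mask=np.ones(est.shape, dtype=bool))
    rng = np.random.default_rng(seed + 1000)
    rows, cols = est.shape
    targets = np.column_stack([
        rng.integers(margin, rows - margin, n_targets),
        rng.integers(margin, cols - margin, n_targets)])
    refs = tilt_map[targets[:, 0], targets[:, 1]]
    return SceneStimuli(local_map=lm, geometry=geom, targets=targets,
                        references=refs, groundtruth_map=tilt_map)


class TestMeanError:
    def test_identical_lists_zero(self):
        assert mean_error([10.0, 200.0], [10.0, 200.0]) == pytest.approx(0.0)

    def test_constant_thirty_under_both_aggregations(self):
        est = np.array([40.0, 130.0, 220.0])
        ref = est - 30.0
        assert mean_error(est, ref) == pytest.approx(30.0, abs=1e-9)
        assert mean_error(est, ref, "arithmetic") == pytest.approx(30.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        est = rng.uniform(0, 360, 200)
        ref = rng.uniform(0, 360, 200)
        d = abs_diff(est, ref)
        want = weighted_phasor_mean(d, np.ones_like(d))
        assert mean_error(est, ref) == pytest.approx(want, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_error([], [])


class TestSweep:
    def test_zero_diameter_equals_local_error_exactly(self, geom):
        tilt, _ = generate_patchwork_tilt_map((96, 96), seed=1)
        stim = _stimuli(tilt, 25.0, seed=2, geom=geom)
        curve = sweep_diameters([stim], [0.0, 8.0])
        local_err = mean_error(
            stim.local_map.tilt_estimate[stim.targets[:, 0], stim.targets[:, 1]],
            stim.references)
        assert curve.mean_error[0] == pytest.approx(local_err, abs=1e-12)

    def test_curve_independent_of_diameter_order(self, geom):
        tilt, _ = generate_patchwork_tilt_map((96, 96), seed=3)
        stim = _stimuli(tilt, 25.0, seed=4, geom=geom)
        a = sweep_diameters([stim], [0.0, 6.0, 12.0]).mean_error
        e12, _ = per_target_errors([stim], 12.0)
        e6, _ = per_target_errors([stim], 6.0)
        assert mean_error(e12[np.isfinite(e12)],
                          np.zeros(np.isfinite(e12).sum())) \
            == pytest.approx(a[2])
        assert mean_error(e6[np.isfinite(e6)],
                          np.zeros(np.isfinite(e6).sum())) \
            == pytest.approx(a[1])

    def test_diameters_must_increase(self, geom):
        from tiltpool.evaluation import ErrorCurve
        with pytest.raises(ValueError):
            ErrorCurve(diameters=np.array([4.0, 2.0]),
                       mean_error=np.array([1.0, 1.0]))


class TestBootstrap:
    def test_constant_errors_zero_width(self):
        lo, hi = bootstrap_ci(np.full(50, 12.0), n_sets=200, seed=0)
        assert lo == pytest.approx(12.0) and hi == pytest.approx(12.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            errs = rng.uniform(0, 60, 80)
            point = mean_error(errs, np.zeros_like(errs))
            lo, hi = bootstrap_ci(errs, n_sets=500, seed=trial)
            assert lo <= point <= hi

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        errs = rng.uniform(0, 40, 60)
        assert bootstrap_ci(errs, seed=5) == bootstrap_ci(errs, seed=5)

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        small = rng.uniform(0, 50, 100)
        large = rng.uniform(0, 50, 400)
        lo_s, hi_s = bootstrap_ci(small, n_sets=800, seed=7)
        lo_l, hi_l = bootstrap_ci(large, n_sets=800, seed=7)
        assert (hi_l - lo_l) < (hi_s - lo_s)


class TestBestDiameterPerTilt:
    def test_tie_breaks_to_smallest_diameter(self, geom):
        # constant local map: every diameter gives zero error -> ties
        lm = LocalEstimateMap(tilt_estimate=np.full((96, 96), 42.0),
                              defined_mask=np.ones((96, 96), bool))
        rng = np.random.default_rng(4)
        targets = np.column_stack([rng.integers(12, 84, 48),
                                   rng.integers(12, 84, 48)])
        refs = np.full(48, 42.0)
        # spread references over bins artificially via keys
        refs_binned = np.mod(np.arange(48) * 7.5, 360.0)
        stim = SceneStimuli(local_map=lm, geometry=geom, targets=targets,
                            references=refs_binned,
                            groundtruth_map=np.full((96, 96), 42.0))
        table = best_diameter_per_tilt([stim], [0.0, 4.0, 8.0], n_bins=24,
                                       mode="fixed")
        # per-target errors identical across diameters -> smallest chosen
        assert (table["best_diameter"] == 0.0).all()

    def test_degenerate_constant_vectors_flagged(self):
        r, p = diameter_correlation(np.full(24, 30.0), np.arange(24.0))
        assert np.isnan(r) and np.isnan(p)

    def test_correlation_detects_matched_scales(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(10, 60, 24)
        best = pred * 1.2 + rng.normal(0, 2.0, 24)
        r, p = diameter_correlation(best, pred, n_perm=2000, seed=6)
        assert r > 0.9 and p < 0.01

    def test_empty_bin_rejected(self, geom):
        lm = LocalEstimateMap(tilt_estimate=np.zeros((96, 96)),
                              defined_mask=np.ones((96, 96), bool))
        stim = SceneStimuli(local_map=lm, geometry=geom,
                            targets=np.array([[40, 40]]),
                            references=np.array([5.0]))
        with pytest.raises(ValueError, match="bin"):
            best_diameter_per_tilt([stim], [0.0, 4.0], n_bins=24, mode="fixed")


class TestReliability:
    def test_perfect_estimates_give_delta_conditionals(self):
        rng = np.random.default_rng(6)
        gt = rng.uniform(0, 360, 5000)
        table, score = reliability_diagnostic(gt, gt)
        # each conditional concentrates all mass in the two groundtruth bins
        # overlapping its estimate bin (12 estimate bins vs 24 gt bins)
        ok = ~np.isnan(table).any(axis=1)
        assert ((table[ok] > 0).sum(axis=1) <= 2).all()
        assert score < 0.05

    def test_shifted_noise_is_shift_invariant(self):
        rng = np.random.default_rng(7)
        est = rng.uniform(0, 360, 40000)
        gt = np.mod(est + rng.normal(0, 20.0, est.size), 360.0)
        table, score = reliability_diagnostic(est, gt)
        assert score < 0.1

    def test_rows_normalized(self):
        rng = np.random.default_rng(8)
        est = rng.uniform(0, 360, 2000)
        gt = rng.uniform(0, 360, 2000)
        table, _ = reliability_diagnostic(est, gt)
        ok = ~np.isnan(table).any(axis=1)
        assert np.allclose(table[ok].sum(axis=1), 1.0)


class TestConsensus:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["stimulus", "observer", "estimate"])

    def test_identical_observers_return_estimate(self):
        df = self._frame([(0, "a", 70.0), (0, "b", 70.0)])
        out = consensus_baseline(df)
        assert out["consensus"][0] == pytest.approx(70.0)

    def test_symmetric_pair_averages(self):
        df = self._frame([(0, "a", 80.0), (0, "b", 100.0)])
        assert consensus_baseline(df)["consensus"][0] == pytest.approx(90.0)

    def test_matches_bruteforce_phasor(self):
        rng = np.random.default_rng(9)
        ests = rng.uniform(0, 360, 5)
        df = self._frame([(0, f"o{k}", e) for k, e in enumerate(ests)])
        want = weighted_phasor_mean(ests, np.ones(5))
        assert consensus_baseline(df)["consensus"][0] == pytest.approx(want)

    def test_antipodal_pair_flagged_degenerate(self):
        df = self._frame([(0, "a", 10.0), (0, "b", 190.0)])
        out = consensus_baseline(df)
        assert out["degenerate"][0]
        assert np.isnan(out["consensus"][0])

    def test_single_observer_rejected(self):
        with pytest.raises(ValueError):
            consensus_baseline(self._frame([(0, "a", 10.0)]))


def test_prediction_error_minimized_near_generating_diameter(geom):
    """A simulated observer built from the global model at a given pooling
    diameter is best predicted at (or adjacent to) that diameter."""
    from tiltpool.pooling import estimate_global
    gen_d = 12.0
    diameters = [0.0, 6.0, 12.0, 24.0, 48.0]
    stimuli = []
    for seed in range(3):
        tilt, _ = generate_patchwork_tilt_map((96, 96), seed=seed,
                                              mean_diameter_px=28.0)
        stim = _stimuli(tilt, 40.0, seed=seed + 10, geom=geom)
        model_est = estimate_global(stim.local_map, geom, mode="fixed",
                                    diameter_arcmin=gen_d,
                                    targets=stim.targets)
        rng = np.random.default_rng(seed + 20)
        observer = np.mod(model_est + rng.normal(0, 5.0, model_est.size), 360.0)
        stimuli.append(SceneStimuli(local_map=stim.local_map, geometry=geom,
                                    targets=stim.targets, references=observer,
                                    groundtruth_map=tilt))
    curve = sweep_diameters(stimuli, diameters, kind="prediction")
    best = diameters[int(np.argmin(curve.mean_error))]
    assert best in (6.0, 12.0, 24.0)
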