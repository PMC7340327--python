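import numpy as np
import pytest

from helpers import weighted_phasor_mean
from tiltpool.circstats import abs_diff
from tiltpool.geometry import ViewingGeometry
from tiltpool.lut import LocalEstimateMap
from tiltpool.pooling import (circular_region, elliptical_region,
                              estimate_global, pool)
from tiltpool.statistics import PoolingSpec


@pytest.fixture
def geom():
    return ViewingGeometry(pixel_scale=1.0, fixation_distance_m=10.0,
                           image_size=(64, 64))


def _local(tilts, defined=None):
    tilts = np.asarray(tilts, dtype=float)
    if defined is None:
        defined = np.ones(tilts.shape, dtype=bool)
    return LocalEstimateMap(tilt_estimate=tilts, defined_mask=defined)


class TestCircularRegion:
    def test_zero_diameter_single_pixel(self, geom):
        region = circular_region(0.0, geom)
        assert region.offsets.shape == (1, 2)
        assert region.weights[0] == 1.0

    def test_pixel_count_approximates_disk_area(self, geom):
        d = 20.0  # arcmin = px here
        region = circular_region(d, geom)
        want = np.pi * (d / 2.0) ** 2
        assert abs(len(region.offsets) - want) / want < 0.05

    def test_equal_weights(self, geom):
        region = circular_region(11.0, geom)
        assert np.allclose(region.weights, 1.0 / len(region.offsets))

    def test_negative_diameter_rejected(self, geom):
        with pytest.raises(ValueError):
            circular_region(-1.0, geom)


class TestEllipticalRegion:
    def test_isotropic_spec_equals_circle(self, geom):
        spec = PoolingSpec.isotropic(24, dbar=16.0)
        er = elliptical_region(40.0, 16.0, spec, geom)
        cr = circular_region(16.0, geom)
        assert np.array_equal(np.sort(er.offsets, axis=0),
                              np.sort(cr.offsets, axis=0))

    def test_average_area_matches_circle(self, geom):
        rng = np.random.default_rng(0)
        rel = rng.uniform(0.5, 1.5, 24)
        rel = rel / rel.mean()
        spec = PoolingSpec(n_bins=24, relative_area=rel,
                           aspect_ratio=np.full(24, 1.6),
                           orientation=(np.arange(24) * 15.0 + 90.0) % 180.0,
                           fitted_dbar=20.0)
        dbar = 20.0
        counts = [len(elliptical_region(spec.bin_centers[b], dbar, spec,
                                        geom).offsets) for b in range(24)]
        want = np.pi * (dbar / 2.0) ** 2
        assert abs(np.mean(counts) - want) / want < 0.05

    def test_orthogonal_elongation_at_tilt_zero(self, geom):
        spec = PoolingSpec(n_bins=24, relative_area=np.ones(24),
                           aspect_ratio=np.full(24, 2.0),
                           orientation=(np.arange(24) * 15.0 + 7.5 + 90.0) % 180.0,
                           fitted_dbar=16.0)
        region = elliptical_region(0.0, 16.0, spec, geom)
        dx, dy = region.offsets[:, 0], region.offsets[:, 1]
        # major axis should be (near-)vertical
        assert np.abs(dy).max() > np.abs(dx).max()


class TestPool:
    def test_constant_map_returns_constant(self, geom):
        lm = _local(np.full((64, 64), 123.0))
        val, flag = pool(lm, circular_region(12.0, geom), (32, 32))
        assert flag == "ok"
        assert val == pytest.approx(123.0)

    def test_single_pixel_region_is_local_estimate(self, geom):
        rng = np.random.default_rng(1)
        lm = _local(rng.uniform(0, 360, (64, 64)))
        val, flag = pool(lm, circular_region(0.0, geom), (10, 20))
        assert val == lm.tilt_estimate[10, 20]

    def test_matches_bruteforce_phasor_mean(self, geom):
        rng = np.random.default_rng(2)
        lm = _local(rng.uniform(0, 360, (64, 64)))
        region = circular_region(14.0, geom)
        val, _ = pool(lm, region, (30, 30))
        angles = [lm.tilt_estimate[30 + dy, 30 + dx]
                  for dx, dy in region.offsets]
        want = weighted_phasor_mean(angles, region.weights)
        assert abs_diff(val, want) <= 1e-9

    def test_degenerate_resultant_falls_back_to_target(self, geom):
        tilts = np.zeros((64, 64))
        tilts[32, 31] = 0.0
        tilts[32, 33] = 180.0
        lm = _local(tilts, defined=np.zeros((64, 64), bool))
        lm.defined_mask[32, 31] = lm.defined_mask[32, 33] = True
        lm.defined_mask[32, 32] = True
        lm.tilt_estimate[32, 32] = 55.0
        region = circular_region(2.0, geom)
        # exclude the target itself from the antipodal pair by weights:
        # the three defined pixels give resultant from 0,180,55
        val, flag = pool(lm, region, (32, 32))
        assert flag == "ok"  # 55 breaks the tie
        lm.defined_mask[32, 32] = False
        lm2 = _local(tilts, defined=lm.defined_mask)
        val2, flag2 = pool(lm2, region, (32, 32))
        assert flag2 in ("degenerate", "undefined")


class TestEstimateGlobal:
    def test_zero_diameter_reproduces_local_exactly(self, geom):
        rng = np.random.default_rng(3)
        lm = _local(rng.uniform(0, 360, (64, 64)))
        est = estimate_global(lm, geom, mode="fixed", diameter_arcmin=0.0)
        assert np.array_equal(est, lm.tilt_estimate)

    def test_adaptive_isotropic_equals_fixed(self, geom):
        rng = np.random.default_rng(4)
        lm = _local(rng.uniform(0, 360, (64, 64)))
        gt = rng.uniform(0, 360, (64, 64))
        spec = PoolingSpec.isotropic(24)
        targets = np.column_stack([rng.integers(8, 56, 40),
                                   rng.integers(8, 56, 40)])
        fixed = estimate_global(lm, geom, mode="fixed", diameter_arcmin=10.0,
                                targets=targets)
        adaptive = estimate_global(lm, geom, mode="adaptive",
                                   diameter_arcmin=10.0, spec=spec,
                                   key_mode="groundtruth", key_tilt=gt,
                                   targets=targets)
        assert np.allclose(fixed, adaptive)

    def test_pooling_reduces_noise_on_constant_patch(self, geom):
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 30.0, (64, 64))
        lm = _local(np.mod(200.0 + noise, 360.0))
        targets = np.column_stack([rng.integers(16, 48, 50),
                                   rng.integers(16, 48, 50)])
        err0 = abs_diff(estimate_global(lm, geom, diameter_arcmin=0.0,
                                        targets=targets), 200.0).mean()
        err10 = abs_diff(estimate_global(lm, geom, diameter_arcmin=10.0,
                                         targets=targets), 200.0).mean()
        assert err10 < err0

    def test_estimate_keyed_adaptive_runs_single_pass(self, geom):
        rng = np.random.default_rng(6)
        lm = _local(rng.uniform(0, 360, (64, 64)))
        spec = PoolingSpec.isotropic(24)
        targets = np.array([[32, 32], [20, 40]])
        est = estimate_global(lm, geom, mode="adaptive", diameter_arcmin=8.0,
                              spec=spec, key_mode="local_estimate",
                              targets=targets)
        assert np.isfinite(est).all()
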