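import numpy as np
import pytest

from tiltpool.circstats import abs_diff
from tiltpool.cues import QuantizedCues, dequantize
from tiltpool.geometry import TiltMap
from tiltpool.lut import (PROV_CELL, PROV_DU_MARGINAL, PROV_PRIOR,
                          LookupTables, area_matched_sigma, estimate_local,
                          train_luts)


def _qcues(lum, tex, disp, disp_s, defined=None):
    lum = np.asarray(lum)
    if defined is None:
        defined = np.ones(lum.shape, dtype=bool)
    return QuantizedCues(lum_u=lum, tex_u=np.asarray(tex),
                         disp_u=np.asarray(disp), disp_s=np.asarray(disp_s),
                         defined_mask=defined)


def _tilt_map(tilt_signed, defined=None):
    t = np.asarray(tilt_signed, dtype=float)
    if defined is None:
        defined = np.ones(t.shape, dtype=bool)
    return TiltMap(tilt_signed=t, tilt_unsigned=t % 180.0,
                   slant=np.zeros_like(t), defined_mask=defined)


def test_single_training_pixel_sets_cell_mean():
    q = _qcues([[3]], [[5]], [[7]], [[9]])
    luts = train_luts([(q, _tilt_map([[37.0]]))])
    assert luts.unsigned_means()[3, 5, 7] == pytest.approx(37.0, abs=1e-9)
    assert luts.unsigned_count[3, 5, 7] == 1


def test_two_pixels_in_one_cell_average_circularly():
    q = _qcues([[3, 3]], [[5, 5]], [[7, 7]], [[9, 9]])
    luts = train_luts([(q, _tilt_map([[30.0, 60.0]]))])
    assert luts.unsigned_means()[3, 5, 7] == pytest.approx(45.0, abs=1e-9)


def test_cell_means_match_bruteforce_recomputation():
    rng = np.random.default_rng(0)
    n = 4000
    lum, tex, disp = (rng.integers(0, 8, n) for _ in range(3))
    disp_s = rng.integers(0, 64, n)
    tilt = rng.uniform(0, 180, n)
    q = _qcues(lum[None, :], tex[None, :], disp[None, :], disp_s[None, :])
    luts = train_luts([(q, _tilt_map(tilt[None, :]))])
    means = luts.unsigned_means()
    for cell in [(0, 0, 0), (3, 5, 7), (7, 7, 7)]:
        sel = (lum == cell[0]) & (tex == cell[1]) & (disp == cell[2])
        if not sel.any():
            continue
        z = np.exp(1j * np.deg2rad(tilt[sel])).sum()
        want = abs(np.rad2deg(np.angle(z)))
        assert abs_diff(means[cell], want, 180.0) <= 0.01


def test_merge_equals_joint_training_exactly():
    rng = np.random.default_rng(1)

    def random_pair(seed):
        r = np.random.default_rng(seed)
        shape = (8, 8)
        return (_qcues(r.integers(0, 64, shape), r.integers(0, 64, shape),
                       r.integers(0, 64, shape), r.integers(0, 64, shape)),
                _tilt_map(r.uniform(0, 360, shape)))

    pa, pb = random_pair(10), random_pair(11)
    joint = train_luts([pa, pb])
    merged = train_luts([pa]) + train_luts([pb])
    assert np.array_equal(joint.unsigned_phasor, merged.unsigned_phasor)
    assert np.array_equal(joint.unsigned_count, merged.unsigned_count)
    assert np.array_equal(joint.sign_phasor, merged.sign_phasor)
    assert joint.prior_phasor == merged.prior_phasor


def test_no_defined_training_pixels_raises():
    q = _qcues([[0]], [[0]], [[0]], [[0]], defined=np.zeros((1, 1), bool))
    with pytest.raises(ValueError):
        train_luts([(q, _tilt_map([[10.0]]))])


class TestEstimateLocal:
    def test_sign_composition(self):
        # unsigned mean 120 with positive-sign and negative-sign cells
        q_pos = _qcues([[1]], [[2]], [[3]], [[0]])
        luts = train_luts([(q_pos, _tilt_map([[120.0]]))])
        est = estimate_local(q_pos, luts)
        assert est.tilt_estimate[0, 0] == pytest.approx(120.0)

        q_neg = _qcues([[1]], [[2]], [[3]], [[1]])
        luts2 = train_luts([(q_neg, _tilt_map([[240.0]]))])  # mean sign < 0
        est2 = estimate_local(q_neg, luts2)
        # magnitude of 240 deg is 120; sign negative -> -120 = 240
        assert luts2.unsigned_means()[1, 2, 3] == pytest.approx(120.0)
        assert est2.tilt_estimate[0, 0] == pytest.approx(240.0)

    def test_zero_magnitude_estimate_fixed_point(self):
        # magnitude 0 maps to 0 under either sign; magnitude 180 to 180
        q = _qcues([[1]], [[2]], [[3]], [[1]])
        luts = train_luts([(q, _tilt_map([[0.0]]))])
        assert estimate_local(q, luts).tilt_estimate[0, 0] == pytest.approx(0.0)
        luts2 = train_luts([(q, _tilt_map([[180.0]]))])
        assert estimate_local(q, luts2).tilt_estimate[0, 0] == pytest.approx(180.0)

    def test_fallback_provenance_chain(self):
        train_q = _qcues([[1]], [[2]], [[3]], [[0]])
        luts = train_luts([(train_q, _tilt_map([[40.0]]))])
        # same D_u bin, different lum/tex -> du-marginal fallback
        test_q = _qcues([[9, 1]], [[9, 2]], [[3, 3]], [[0, 0]])
        est = estimate_local(test_q, luts)
        assert est.provenance[0, 1] == PROV_CELL
        assert est.provenance[0, 0] == PROV_DU_MARGINAL
        assert est.tilt_estimate[0, 0] == pytest.approx(40.0)
        # unseen D_u bin as well -> global prior mean
        test_q2 = _qcues([[9]], [[9]], [[9]], [[0]])
        est2 = estimate_local(test_q2, luts)
        assert est2.provenance[0, 0] == PROV_PRIOR
        assert est2.tilt_estimate[0, 0] == pytest.approx(40.0)

    def test_binwise_deterministic_mapping_recovered_on_heldout(self):
        # tilt is a deterministic, bin-resolvable function of the cue
        # triplet: held-out pixels must recover unsigned tilt exactly
        rng = np.random.default_rng(2)
        n_bins = 8
        mapping = rng.uniform(0, 180, (n_bins, n_bins, n_bins))
        sign_map = np.where(rng.random(64) < 0.5, 1.0, -1.0)

        def draw(seed, n):
            r = np.random.default_rng(seed)
            l, t, d = (r.integers(0, n_bins, n) for _ in range(3))
            ds = r.integers(0, 64, n)
            tu = mapping[l, t, d]
            ts = np.mod(tu * sign_map[ds], 360.0)
            return _qcues(l[None], t[None], d[None], ds[None]), _tilt_map(ts[None])

        luts = train_luts([draw(0, 20000)])
        q_test, tilt_test = draw(1, 2000)
        est = estimate_local(q_test, luts)
        from tiltpool.circstats import signed_diff
        got_mag = np.abs(signed_diff(est.tilt_estimate, 0.0, 360.0))
        want_mag = np.abs(signed_diff(tilt_test.tilt_signed, 0.0, 360.0))
        half_bin = 180.0 / 64 / 2.0
        assert np.max(np.abs(got_mag - want_mag)) <= half_bin


def test_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    shape = (16, 16)
    q = _qcues(rng.integers(0, 64, shape), rng.integers(0, 64, shape),
               rng.integers(0, 64, shape), rng.integers(0, 64, shape))
    luts = train_luts([(q, _tilt_map(rng.uniform(0, 360, shape)))])
    path = tmp_path / "luts.h5"
    luts.save(path)
    back = LookupTables.load(path)
    assert np.array_equal(back.unsigned_phasor, luts.unsigned_phasor)
    assert np.array_equal(back.sign_count, luts.sign_count)
    assert back.prior_count == luts.prior_count
    assert back.angle_doubling == luts.angle_doubling


def test_angle_doubling_alternative_estimator():
    q = _qcues([[1, 1]], [[2, 2]], [[3, 3]], [[0, 0]])
    tilt = _tilt_map([[5.0, 175.0]])  # axial data wrapping around 0
    printed = train_luts([(q, tilt)])
    doubled = train_luts([(q, tilt)], angle_doubling=True)
    # the axial estimator averages 5 and 175 to 0 (mod 180); the printed
    # raw-phasor form lands at 90
    assert abs_diff(doubled.unsigned_means()[1, 2, 3], 0.0, 180.0) < 1e-9
    assert printed.unsigned_means()[1, 2, 3] == pytest.approx(90.0, abs=1e-9)


def test_area_matched_sigma_scales_support():
    # support diameter = 6 sigma; a 1 degree target gives sigma = 10 arcmin
    assert area_matched_sigma(1.0) == pytest.approx(10.0)
    assert area_matched_sigma(0.6) == pytest.approx(6.0)
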