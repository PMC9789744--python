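import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvos.curves import HemodynamicCurveParams, simulate_hbt_curve
from dvos.features import (
    AngiosomeTree,
    FeatureError,
    TrialFeatures,
    difference_features,
    extract_trial_features,
    features_table,
    gen_loc_aggregate,
    patch_features,
    patch_pt,
    PatientFeatures,
)
from dvos.optics import forward_optics, reconstruct_recording
from dvos.protocol import TrialWindow


def _series(t, y):
    from dvos.series import ChromophoreSeries

    return ChromophoreSeries(np.asarray(t, float), 0.5 * np.asarray(y, float),
                             0.5 * np.asarray(y, float))


def trapezoid(rate=10.0):
    """0 -> 10 uM over [0,10] s, hold over [10,70] s, fall to 0 over [70,80] s."""
    t = np.arange(0.0, 80.0 + 1e-9, 1.0 / rate)
    y = np.interp(t, [0.0, 10.0, 70.0, 80.0], [0.0, 10.0, 10.0, 0.0])
    return t, y


def triangle(rate=10.0):
    t = np.arange(0.0, 20.0 + 1e-9, 1.0 / rate)
    y = np.interp(t, [0.0, 10.0, 20.0], [0.0, 10.0, 0.0])
    return t, y


class TestPlateauTimeExtraction:
    def test_trapezoid_analytic_crossings(self, make_series, simple_window):
        t, y = trapezoid()
        feats = extract_trial_features(make_series(t, y), simple_window, smooth_frames=1)
        assert feats.hbt_max_uM == pytest.approx(10.0, abs=1e-12)
        assert feats.t_rise_s == pytest.approx(9.0, abs=1e-9)
        assert feats.pt_s == pytest.approx(62.0, abs=1e-9)
        assert feats.saturated and not feats.right_censored

    def test_triangle_analytic_crossings(self, make_series):
        t, y = triangle()
        window = TrialWindow(60.0, 0.0, 5.0, 15.0, 20.0)
        feats = extract_trial_features(make_series(t, y), window, smooth_frames=1)
        assert feats.pt_s == pytest.approx(2.0, abs=1e-9)
        assert not feats.saturated  # above 90% for only 2 s

    def test_flat_curve_marked_undefined(self, make_series, simple_window):
        t = np.arange(0.0, 80.0, 0.1)
        feats = extract_trial_features(
            make_series(t, np.full_like(t, 3.0)), simple_window, smooth_frames=1
        )
        assert not feats.defined
        assert np.isnan(feats.pt_s)
        assert "flat" in feats.diagnostic

    def test_censored_when_curve_never_drops(self, make_series, simple_window):
        t = np.arange(0.0, 80.0, 0.1)
        y = t / 80.0 * 10.0  # still climbing at window end
        feats = extract_trial_features(make_series(t, y), simple_window, smooth_frames=1)
        assert feats.right_censored
        # t2 clamps to the window end
        assert feats.pt_s == pytest.approx(80.0 - 0.9 * 80.0, abs=0.2)

    def test_too_few_frames_rejected(self, make_series, simple_window):
        t = np.arange(0.0, 80.0, 20.0)
        with pytest.raises(FeatureError):
            extract_trial_features(make_series(t, t), simple_window)

    @settings(max_examples=30, deadline=None)
    @given(
        scale=st.floats(0.05, 20.0, allow_nan=False),
        offset=st.floats(-8.0, 8.0, allow_nan=False),
    )
    def test_pt_invariant_under_positive_affine_rescaling(self, scale, offset):
        t, y = trapezoid()
        window = TrialWindow(60.0, 0.0, 10.0, 70.0, 80.0)
        base = extract_trial_features(_series(t, y), window, smooth_frames=5)
        scaled = extract_trial_features(
            _series(t, scale * y + offset), window, smooth_frames=5
        )
        assert scaled.pt_s == pytest.approx(base.pt_s, abs=1e-9)
        assert scaled.t_rise_s == pytest.approx(base.t_rise_s, abs=1e-9)

    def test_pt_stable_under_finer_resampling(self, schedule):
        params = HemodynamicCurveParams(target_pt_s=35.0)
        coarse = simulate_hbt_curve(params, schedule, 2.56)
        fine = simulate_hbt_curve(params, schedule, 10.24)
        trial = schedule.trials[0]
        pt_c = extract_trial_features(coarse, trial, smooth_frames=1).pt_s
        pt_f = extract_trial_features(fine, trial, smooth_frames=1).pt_s
        assert abs(pt_c - pt_f) <= 2.0 / 2.56

    def test_noisy_simulator_curve_recovers_target_pt(self, schedule):
        """Full optics round trip at the 4-patch frame rate, 1% noise."""
        params = HemodynamicCurveParams(target_pt_s=30.0)
        series = simulate_hbt_curve(params, schedule, 2.56)
        rec = forward_optics(
            series, schedule=schedule, frame_rate_hz=2.56, noise_rel_sd=0.01, rng=0
        )
        for feats in patch_features(reconstruct_recording(rec), schedule):
            assert feats.pt_s == pytest.approx(30.0, abs=2.0 / 2.56)


class TestPatchAggregation:
    def test_patch_pt_is_mean_of_trials(self):
        trials = [
            TrialFeatures(60.0, 10.0, 5.0, 60.0, True, False),
            TrialFeatures(100.0, 10.0, 5.0, 64.0, True, False),
        ]
        assert patch_pt(trials) == pytest.approx(62.0)

    def test_single_defined_trial_used_with_warning(self):
        trials = [
            TrialFeatures(60.0, 10.0, 5.0, 62.0, True, False),
            TrialFeatures.undefined(100.0, "flat"),
        ]
        with pytest.warns(UserWarning):
            assert patch_pt(trials) == pytest.approx(62.0)

    def test_both_undefined_propagates_missing(self):
        trials = [TrialFeatures.undefined(60.0, "x"), TrialFeatures.undefined(100.0, "y")]
        assert np.isnan(patch_pt(trials))

    def test_equal_trials_idempotent(self):
        trials = [
            TrialFeatures(60.0, 10.0, 5.0, 41.0, True, False),
            TrialFeatures(100.0, 10.0, 5.0, 41.0, True, False),
        ]
        assert patch_pt(trials) == 41.0


class TestGenLocAggregation:
    def test_patch_on_ulcer_angiosome_preferred(self):
        gen, loc = gen_loc_aggregate(
            {"posterior_tibial": 40.0, "dorsalis_pedis": 60.0}, "dorsalis_pedis"
        )
        assert gen == pytest.approx(50.0)
        assert loc == pytest.approx(60.0)

    def test_mean_of_patches_below_affected_artery(self):
        gen, loc = gen_loc_aggregate(
            {"medial_plantar": 30.0, "lateral_plantar": 50.0}, "posterior_tibial"
        )
        assert gen == pytest.approx(40.0)
        assert loc == pytest.approx(40.0)

    def test_patch_directly_above_as_fallback(self):
        _, loc = gen_loc_aggregate({"anterior_tibial": 45.0}, "dorsalis_pedis")
        assert loc == 45.0

    def test_unresolvable_loc_is_missing(self):
        _, loc = gen_loc_aggregate({"peroneal": 33.0}, "dorsalis_pedis")
        assert np.isnan(loc)

    def test_gen_permutation_invariant(self):
        pts = {"peroneal": 10.0, "anterior_tibial": 20.0, "medial_plantar": 60.0}
        rev = dict(reversed(list(pts.items())))
        assert gen_loc_aggregate(pts, "peroneal")[0] == gen_loc_aggregate(rev, "peroneal")[0]

    def test_unknown_ulcer_angiosome_rejected(self):
        with pytest.raises(FeatureError):
            gen_loc_aggregate({"peroneal": 10.0}, "femoral")

    def test_cyclic_tree_rejected(self):
        with pytest.raises(FeatureError):
            AngiosomeTree(parent={"dorsalis_pedis": "anterior_tibial",
                                  "anterior_tibial": "dorsalis_pedis"})


class TestDifferenceFeatures:
    def test_later_minus_earlier(self):
        diffs = difference_features({"Pre": 10.0, "Post": 55.0, "FU1": 61.0})
        assert diffs == {"PostPre": 45.0, "FU1Pre": 51.0, "FU1Post": 6.0}

    def test_equal_time_points_give_zeros(self):
        diffs = difference_features({"Pre": 30.0, "Post": 30.0, "FU1": 30.0})
        assert all(v == 0.0 for v in diffs.values())

    def test_missing_time_point_propagates(self):
        diffs = difference_features({"Post": 55.0, "FU1": 61.0})
        assert np.isnan(diffs["PostPre"]) and np.isnan(diffs["FU1Pre"])
        assert diffs["FU1Post"] == 6.0

    @settings(max_examples=50, deadline=None)
    @given(
        pre=st.floats(0, 100, allow_nan=False),
        post=st.floats(0, 100, allow_nan=False),
        fu1=st.floats(0, 100, allow_nan=False),
    )
    def test_fu1post_identity(self, pre, post, fu1):
        d = difference_features({"Pre": pre, "Post": post, "FU1": fu1})
        assert d["FU1Post"] == pytest.approx(d["FU1Pre"] - d["PostPre"], abs=1e-9)


def test_features_table_layout():
    p = PatientFeatures(
        patient_id="P01", outcome=1,
        pt_gen={"Pre": 10.0, "Post": 55.0, "FU1": 61.0},
        pt_loc={"Pre": 12.0, "Post": 50.0, "FU1": 58.0},
        censored={"FU1": True},
    )
    table = features_table([p])
    row = table.iloc[0]
    assert row["FU1PostGen"] == 6.0
    assert row["FU1PostLoc"] == 8.0
    assert bool(row["censored_FU1"]) is True
    assert {"PT_Pre_Gen", "PostPreGen", "FU1PreLoc"} <= set(table.columns)
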