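import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hoofbeat import (LimbEventSeries, StrideWindow, find_segment_extrema,
                      inclusion_filter, make_template, pair_strides,
                      simulate_trial, symmetry_indices, temporal_variables,
                      find_extrema, analyze_trial)
from hoofbeat.kinematics import DisplacementStride


def _stride_from_function(fn, stance_pct, duration_s=1.0, fs=400.0,
                          segment="head"):
    """Build a DisplacementStride from an analytic z(phase in [0,1))."""
    t = np.arange(int(duration_s * fs) + 1) / fs
    z = fn(t / duration_s)
    w = StrideWindow(0, 0.0, duration_s)
    for limb, (on, off) in stance_pct.items():
        w.onsets[limb] = on / 100.0 * duration_s
        w.offsets[limb] = off / 100.0 * duration_s
    return DisplacementStride(segment=segment, stride_index=0, window=w,
                              normalized=z[:101], raw_t=t, raw_z=z,
                              stance_pct=stance_pct)


FOUR_LIMB = {"LF": (0.0, 50.0), "RF": (50.0, 100.0),
             "LH": (0.0, 50.0), "RH": (50.0, 100.0)}


class TestTemporalVariables:
    def test_ideal_walk_dissociations_and_suspension(self, ideal_walk_trial):
        windows = pair_strides(ideal_walk_trial.events)
        tv = temporal_variables(windows[1], ideal_walk_trial.events, "walk")
        assert tv.diagonal_dissociation_pct == pytest.approx(-25.0, abs=1e-9)
        assert tv.lateral_dissociation_pct == pytest.approx(25.0, abs=1e-9)
        assert tv.suspension_pct == pytest.approx(0.0, abs=1e-9)

    def test_duty_factor_identity_machine_precision(self, wb_trot_trial):
        windows = pair_strides(wb_trot_trial.events)
        for w in windows:
            tv = temporal_variables(w, wb_trot_trial.events, "trot")
            assert (tv.duty_factor_fl * tv.stride_duration_s
                    == pytest.approx(tv.stance_duration_fl_s, abs=1e-12))
            assert (tv.stance_duration_hl_s + tv.swing_duration_hl_s
                    == pytest.approx(tv.stride_duration_s, abs=1e-12))

    def test_warmblood_trot_duty_factor_matches_published(self, wb_trot_table):
        # 0.38 / 0.78 = 0.487, published median 0.49
        assert wb_trot_table.duty_factor_fl.median() == pytest.approx(
            0.49, abs=0.01)
        assert wb_trot_table.duty_factor_hl.median() == pytest.approx(
            0.39, abs=0.01)

    def test_synchronous_pace_suspension(self):
        """Lateral pairs move together, stance 0.15 s, half-stride 0.21 s:
        suspension is 2 x (0.21 - 0.15) / 0.42 = 28.6 %StrD."""
        T, half, stance = 0.42, 0.21, 0.15
        ons_l = np.arange(5) * T
        ons_r = ons_l + half
        events = {
            "LH": LimbEventSeries("LH", ons_l, ons_l + stance),
            "LF": LimbEventSeries("LF", ons_l, ons_l + stance),
            "RH": LimbEventSeries("RH", ons_r, ons_r + stance),
            "RF": LimbEventSeries("RF", ons_r, ons_r + stance),
        }
        w = pair_strides(events)[1]
        tv = temporal_variables(w, events, "pace")
        assert tv.suspension_pct == pytest.approx(100 * 2 * (half - stance) / T,
                                                  abs=1e-9)
        assert tv.lateral_dissociation_pct == pytest.approx(0.0, abs=1e-9)

    def test_walk_lateral_minus_diagonal_is_fifty(self, ideal_walk_table):
        d = (ideal_walk_table.lateral_dissociation_pct
             - ideal_walk_table.diagonal_dissociation_pct)
        np.testing.assert_allclose(d, 50.0, atol=1e-9)

    @pytest.mark.parametrize("gait,condition", [
        ("walk", "warmblood"), ("walk", "iberian"),
        ("walk", "icelandic_inhand"), ("tolt", "icelandic_ridden")])
    def test_no_suspension_in_walk_and_tolt(self, gait, condition):
        trial = simulate_trial(make_template(gait, condition,
                                             n_strides=3, seed=0))
        df = analyze_trial(trial)
        np.testing.assert_allclose(df.suspension_pct, 0.0, atol=1e-9)


class TestFindExtrema:
    def test_sinusoid_min_at_midstance_reads_fifty(self):
        stride = _stride_from_function(
            lambda u: 10.0 * np.cos(4 * np.pi * u), FOUR_LIMB)
        rec = find_segment_extrema(stride)
        assert rec.time_pct_stance[("left", "min")] == pytest.approx(50.0,
                                                                     abs=0.2)
        assert rec.time_pct_stance[("right", "min")] == pytest.approx(50.0,
                                                                      abs=0.2)

    def test_brute_force_oracle_agreement(self):
        """Spline-based extremum search matches dense brute force on random
        smooth two-cycle strides."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            a1, a3 = rng.uniform(0, 0.25, 2)
            p1, p2, p3 = rng.uniform(0, 2 * np.pi, 3)

            def fn(u):
                return (20 * np.cos(4 * np.pi * u + p2)
                        + 20 * a1 * np.cos(2 * np.pi * u + p1)
                        + 20 * a3 * np.cos(6 * np.pi * u + p3))

            stride = _stride_from_function(fn, FOUR_LIMB)
            rec = find_segment_extrema(stride)
            dense_u = np.linspace(0, 1, 40001, endpoint=False)
            dense = fn(dense_u)
            got_min = min(rec.value_mm[("left", "min")],
                          rec.value_mm[("right", "min")])
            got_max = max(rec.value_mm[("left", "max")],
                          rec.value_mm[("right", "max")])
            assert got_min == pytest.approx(dense.min() - dense.mean(),
                                            abs=0.05)
            assert got_max == pytest.approx(dense.max() - dense.mean(),
                                            abs=0.05)
            best = 100 * dense_u[np.argmin(dense)]
            got_t = min((rec.time_pct_stride[("left", "min")],
                         rec.time_pct_stride[("right", "min")]),
                        key=lambda p: abs((p - best + 50) % 100 - 50))
            assert abs((got_t - best + 50) % 100 - 50) < 0.5

    def test_out_of_stance_pelvis_maximum_reported_past_100(self,
                                                            wb_trot_table):
        assert wb_trot_table.pelvis_max_left_pct_stance.median() == \
            pytest.approx(110.0, abs=1.0)

    def test_indices_invariant_to_constant_offset(self):
        stride = _stride_from_function(
            lambda u: 15 * np.cos(4 * np.pi * u + 0.4), FOUR_LIMB)
        shifted = _stride_from_function(
            lambda u: 15 * np.cos(4 * np.pi * u + 0.4) + 37.0, FOUR_LIMB)
        r0, r1 = find_segment_extrema(stride), find_segment_extrema(shifted)
        s0 = symmetry_indices(type("R", (), {"segments": {"head": r0},
                                             "stride_index": 0})())
        s1 = symmetry_indices(type("R", (), {"segments": {"head": r1},
                                             "stride_index": 0})())
        assert s0.hdmin == pytest.approx(s1.hdmin, abs=1e-6)
        assert s0.romz_mm["head"] == pytest.approx(s1.romz_mm["head"],
                                                   abs=1e-6)


class TestSymmetryIndices:
    def test_symmetric_trot_indices_are_zero(self, wb_trot_table):
        for col in ("HDmin", "HDmax", "WDmin", "WDmax", "PDmin", "PDmax"):
            np.testing.assert_allclose(wb_trot_table[col], 0.0, atol=0.3)

    def test_template_asymmetry_recovered_within_1mm(self):
        tpl = make_template("trot", "warmblood", n_strides=4, seed=0,
                            asymmetry_mm={"HDmin": 12.0})
        df = analyze_trial(simulate_trial(tpl))
        assert df.HDmin.median() == pytest.approx(12.0, abs=1.0)

    def test_published_withers_romz_recovered(self, wb_trot_table):
        assert wb_trot_table.romz_withers_mm.median() == pytest.approx(
            92.2, abs=2.0)


class TestInclusionFilter:
    @pytest.mark.parametrize("hdmin,hdmax,pdmin,pdmax,include,reasons", [
        (16.0, 0.0, 0.0, 0.0, True, ()),          # boundary not exceeded
        (0.0, 16.0, 0.0, 0.0, True, ()),
        (0.0, 0.0, 8.0, 0.0, True, ()),
        (0.0, 0.0, 0.0, -8.0, True, ()),
        (16.01, 0.0, 0.0, 0.0, False, ("HDmin",)),
        (0.0, -16.01, 0.0, 0.0, False, ("HDmax",)),
        (0.0, 0.0, -8.5, 0.0, False, ("PDmin",)),
        (0.0, 0.0, 0.0, 8.01, False, ("PDmax",)),
        (20.0, 3.0, 9.0, 1.0, False, ("HDmin", "PDmin")),
    ])
    def test_threshold_truth_table(self, hdmin, hdmax, pdmin, pdmax,
                                   include, reasons):
        dec = inclusion_filter(hdmin, hdmax, pdmin, pdmax)
        assert dec.include is include
        assert dec.reasons == reasons

    def test_no_trot_data_is_indeterminate(self):
        dec = inclusion_filter(None, 1.0, 1.0, 1.0)
        assert dec.include is None

    @given(st.floats(-40, 40), st.floats(-40, 40),
           st.floats(-20, 20), st.floats(-20, 20))
    def test_decision_depends_only_on_absolute_values(self, a, b, c, d):
        assert (inclusion_filter(a, b, c, d).include
                == inclusion_filter(-a, -b, -c, -d).include)
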