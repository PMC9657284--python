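import numpy as np
import pytest

from hoofbeat import (analyze_trial, inject_asymmetry, make_template,
                      simulate_trial)
from hoofbeat.templates import VALID_PAIRS


def _contact_phases(trial, window_start, window_dur):
    """Contact phase of each limb within one stride, % of stride."""
    out = {}
    for limb, s in trial.events.items():
        sel = (s.hoof_on_s >= window_start) & (s.hoof_on_s
                                               < window_start + window_dur)
        out[limb] = 100.0 * (s.hoof_on_s[sel][0] - window_start) / window_dur
    return out


class TestFootfallRealization:
    def test_ideal_walk_contacts_at_quarter_strides(self, ideal_walk_trial):
        t = ideal_walk_trial.template
        lh = ideal_walk_trial.events["LH"].hoof_on_s
        ph = _contact_phases(ideal_walk_trial, lh[1], lh[2] - lh[1])
        assert ph["LH"] == pytest.approx(0.0, abs=1e-9)
        assert ph["LF"] == pytest.approx(25.0, abs=1e-9)
        assert ph["RH"] == pytest.approx(50.0, abs=1e-9)
        assert ph["RF"] == pytest.approx(75.0, abs=1e-9)

    @pytest.mark.parametrize("gait,condition", VALID_PAIRS)
    def test_intervals_reproduce_template_dissociations(self, gait, condition):
        tpl = make_template(gait, condition, n_strides=3, seed=0)
        trial = simulate_trial(tpl)
        lh = trial.events["LH"].hoof_on_s
        T = lh[1] - lh[0]
        tol = 100.0 / (tpl.fs_hz * T)  # one sample as %StrD
        ph = _contact_phases(trial, lh[1], T)
        expect_lf = tpl.footfall_phases()["LF"]
        assert ph["LF"] == pytest.approx(expect_lf, abs=tol)
        assert ph["RH"] == pytest.approx(50.0, abs=tol)
        assert T == pytest.approx(tpl.stride_duration_s, abs=1e-9)

    def test_degenerate_trot_diagonal_pair_lands_together(self):
        tpl = make_template("trot", "warmblood",
                            {"lateral_dissociation_pct": 50.0,
                             "diagonal_dissociation_pct": 0.0,
                             "n_strides": 3, "seed": 0})
        trial = simulate_trial(tpl)
        lh = trial.events["LH"].hoof_on_s
        rf = trial.events["RF"].hoof_on_s
        # every LH contact coincides with an RF contact
        for t in lh:
            assert np.min(np.abs(rf - t)) < 1e-9


class TestWaveform:
    def test_half_stride_symmetry_when_symmetric(self, wb_trot_trial):
        """Noiseless symmetric gait: z(t + T/2) equals z(t)."""
        T = wb_trot_trial.template.stride_duration_s
        fs = wb_trot_trial.fs_hz
        half = T / 2.0
        for seg, disp in wb_trot_trial.displacement_truth.items():
            t = disp.times()
            core = (t > T) & (t < t[-1] - T - half)
            zi = np.interp(t[core] + half, t, disp.samples)
            np.testing.assert_allclose(zi, disp.samples[core], atol=1e-6)

    def test_two_oscillations_per_stride(self, wb_trot_trial):
        truth = wb_trot_trial.truth_extrema
        per = truth.groupby(["segment", "stride", "kind"]).size()
        assert (per == 2).all()

    def test_extrema_placed_at_template_phases(self, wb_trot_trial):
        tpl = wb_trot_trial.template
        truth = wb_trot_trial.truth_extrema
        lh = wb_trot_trial.events["LH"].hoof_on_s
        for seg in ("head", "withers", "pelvis"):
            ph = tpl.extremum_stride_phases(seg)
            sub = truth[(truth.segment == seg) & (truth.stride == 1)]
            start = lh[np.searchsorted(lh, sub.time_s.min()) - 1]
            for _, r in sub.iterrows():
                got = 100.0 * (r.time_s - start) / tpl.stride_duration_s
                assert got % 100.0 == pytest.approx(
                    ph[(r.side, r.kind)], abs=1e-6)

    def test_acceleration_is_second_derivative_of_truth(self, wb_trot_trial):
        """Finite differences of the truth displacement match the emitted
        acceleration away from arc junctions."""
        for seg in ("head", "pelvis"):
            z = wb_trot_trial.displacement_truth[seg].samples
            a = wb_trot_trial.acceleration[seg].samples * 1000.0
            h = 1.0 / wb_trot_trial.fs_hz
            fd = np.gradient(np.gradient(z, h), h)
            core = slice(10, -10)
            err = np.abs(fd[core] - a[core])
            assert np.median(err) < 0.02 * np.abs(a).max()

    def test_seed_reproducibility_bit_identical(self):
        tpl = make_template("trot", "warmblood", n_strides=3, seed=42,
                            jitter_scale=0.5, noise_sd_mm=1.0)
        t1, t2 = simulate_trial(tpl), simulate_trial(tpl)
        for seg in t1.acceleration:
            np.testing.assert_array_equal(t1.acceleration[seg].samples,
                                          t2.acceleration[seg].samples)
        for limb in t1.events:
            np.testing.assert_array_equal(t1.events[limb].hoof_on_s,
                                          t2.events[limb].hoof_on_s)


class TestInjectAsymmetry:
    def test_zero_delta_is_identity(self, wb_trot_trial):
        out = inject_asymmetry(wb_trot_trial, {"all": 0.0})
        for seg in out.displacement_truth:
            np.testing.assert_array_equal(
                out.displacement_truth[seg].samples,
                wb_trot_trial.displacement_truth[seg].samples)

    def test_unknown_segment_delta_rejected(self, wb_trot_trial):
        with pytest.raises(ValueError, match="unknown"):
            inject_asymmetry(wb_trot_trial, {"XDmin": 3.0})

    def test_head_injection_recovered_and_excluded(self, wb_trot_trial):
        """+20 mm HDmin puts the horse over the 16 mm screen threshold."""
        from hoofbeat import inclusion_filter
        out = inject_asymmetry(wb_trot_trial, {"HDmin": 20.0})
        df = analyze_trial(out)
        assert df.HDmin.median() == pytest.approx(20.0, abs=1.0)
        dec = inclusion_filter(df.HDmin.median(), df.HDmax.median(),
                               df.PDmin.median(), df.PDmax.median())
        assert dec.include is False and "HDmin" in dec.reasons

    def test_small_pelvis_injection_retained(self, wb_trot_trial):
        from hoofbeat import inclusion_filter
        out = inject_asymmetry(wb_trot_trial, {"PDmin": 5.0})
        df = analyze_trial(out)
        assert df.PDmin.median() == pytest.approx(5.0, abs=1.0)
        dec = inclusion_filter(df.HDmin.median(), df.HDmax.median(),
                               df.PDmin.median(), df.PDmax.median())
        assert dec.include is True
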