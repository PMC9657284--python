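import numpy as np
import pytest

from hoofbeat import (AxialTrace, StrideWindow, integrate_displacement,
                      make_template, pair_strides, segment_and_normalize,
                      simulate_trial)


def _sine_trace(A_mm=40.0, f_hz=2.5, n_strides=4, fs=200.0):
    """a(t) = -A w^2 sin(wt) whose displacement is A sin(wt)."""
    w = 2 * np.pi * f_hz
    T = 1.0 / f_hz
    t = np.arange(int(n_strides * T * fs)) / fs
    a = -A_mm * w ** 2 * np.sin(w * t) / 1000.0  # m/s^2
    trace = AxialTrace("head", "acceleration_mps2", fs, a)
    windows = [StrideWindow(i, i * T, (i + 1) * T) for i in range(n_strides)]
    return trace, windows, A_mm


class TestIntegration:
    def test_closed_form_sinusoid_amplitude_within_1pct(self):
        trace, windows, A = _sine_trace()
        disp = integrate_displacement(trace, windows)
        z = disp.samples[np.isfinite(disp.samples)]
        romz = z.max() - z.min()
        assert romz == pytest.approx(2 * A, rel=0.01)

    def test_zero_acceleration_gives_zero_displacement(self):
        trace, windows, _ = _sine_trace()
        trace.samples[:] = 0.0
        disp = integrate_displacement(trace, windows)
        z = disp.samples[np.isfinite(disp.samples)]
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_short_window_dropped(self):
        trace, windows, _ = _sine_trace()
        windows.append(StrideWindow(9, 0.0, 0.01))
        disp = integrate_displacement(trace, windows)
        assert np.isfinite(disp.samples).any()

    def test_simulated_trot_rms_below_2pct_of_romz(self, wb_trot_trial):
        windows = pair_strides(wb_trot_trial.events)
        for seg, acc in wb_trot_trial.acceleration.items():
            romz = wb_trot_trial.template.romz_mm[seg]
            disp = integrate_displacement(acc, windows)
            truth = wb_trot_trial.displacement_truth[seg].samples
            t = disp.times()
            for w in windows:
                m = (t >= w.start_s) & (t < w.end_s)
                zt = truth[m] - truth[m].mean()
                err = np.sqrt(np.mean((disp.samples[m] - zt) ** 2))
                assert err < 0.02 * romz

    def test_oracle_spectral_integration_agrees(self):
        """Trapezoid+per-stride-mean vs independent Fourier-domain double
        integration on a band-limited stride-periodic signal."""
        fs, T, n = 200.0, 0.8, 6
        t = np.arange(int(n * T * fs)) / fs
        w0 = 2 * np.pi / T
        rng = np.random.default_rng(5)
        amps, phs = rng.uniform(5, 30, 3), rng.uniform(0, 2 * np.pi, 3)
        a_mm = sum(-A * ((k + 1) * w0) ** 2 * np.sin((k + 1) * w0 * t + p)
                   for k, (A, p) in enumerate(zip(amps, phs)))
        z_true = sum(A * np.sin((k + 1) * w0 * t + p)
                     for k, (A, p) in enumerate(zip(amps, phs)))
        # independent oracle: FFT division by -omega^2
        freqs = np.fft.rfftfreq(t.size, 1 / fs) * 2 * np.pi
        spec = np.fft.rfft(a_mm)
        spec[1:] /= -freqs[1:] ** 2
        spec[0] = 0.0
        z_fft = np.fft.irfft(spec, t.size)
        windows = [StrideWindow(i, i * T, (i + 1) * T) for i in range(n)]
        trace = AxialTrace("head", "acceleration_mps2", fs, a_mm / 1000.0)
        disp = integrate_displacement(trace, windows)
        scale = np.sqrt(np.mean(z_true ** 2))
        for z_other in (z_fft, z_true):
            for w in windows[1:-1]:
                m = (t >= w.start_s) & (t < w.end_s)
                # centre both by the same sample mean: the DC convention is
                # not part of the comparison
                zo = z_other[m] - z_other[m].mean()
                zp = disp.samples[m] - disp.samples[m].mean()
                rms = np.sqrt(np.mean((zp - zo) ** 2))
                assert rms < 0.01 * scale


class TestNormalization:
    def test_fixed_length_for_unequal_strides(self):
        tpl = make_template("trot", "warmblood", n_strides=4, seed=7,
                            jitter_scale=0.5)
        trial = simulate_trial(tpl)
        windows = pair_strides(trial.events)
        durations = {round(w.duration_s, 4) for w in windows}
        assert len(durations) > 1  # jitter produced different durations
        strides = segment_and_normalize(trial.displacement_truth["head"],
                                        windows)
        assert {s.n_points for s in strides} == {101}

    def test_warmblood_trot_stride_gives_101_points(self, wb_trot_trial):
        windows = pair_strides(wb_trot_trial.events)
        strides = segment_and_normalize(
            wb_trot_trial.displacement_truth["head"], windows)
        assert strides[0].n_points == 101
        assert strides[0].raw_t.size == pytest.approx(156, abs=1)

    def test_linear_ramp_preserved(self):
        fs, T = 200.0, 1.0
        t = np.arange(int(3 * T * fs)) / fs
        trace = AxialTrace("head", "displacement_mm", fs, 5.0 * t)
        windows = [StrideWindow(i, i * T, (i + 1) * T) for i in range(3)]
        out = segment_and_normalize(trace, windows, n_points=11)
        for s in out:
            grid = s.window.start_s + s.window.duration_s * np.linspace(0, 1, 11)
            np.testing.assert_allclose(s.normalized,
                                       5.0 * grid - np.mean(5.0 * grid),
                                       atol=1e-9)

    def test_window_beyond_trace_dropped(self):
        fs, T = 200.0, 1.0
        t = np.arange(int(2 * T * fs)) / fs
        trace = AxialTrace("head", "displacement_mm", fs, np.sin(t))
        windows = [StrideWindow(0, 0.0, 1.0), StrideWindow(1, 1.0, 2.5)]
        out = segment_and_normalize(trace, windows)
        assert [s.stride_index for s in out] == [0]

    def test_extremum_timing_preserved_within_half_percent(self, wb_trot_trial):
        """Resampling must not move extrema by more than 0.5 %StrD."""
        windows = pair_strides(wb_trot_trial.events)
        truth = wb_trot_trial.truth_extrema
        strides = segment_and_normalize(
            wb_trot_trial.displacement_truth["pelvis"], windows)
        s = strides[1]
        w = s.window
        sub = truth[(truth.segment == "pelvis")
                    & (truth.time_s >= w.start_s) & (truth.time_s < w.end_s)
                    & (truth.kind == "min")]
        grid_pct = np.linspace(0, 100, 101)
        for _, r in sub.iterrows():
            true_pct = 100 * (r.time_s - w.start_s) / w.duration_s
            # nearest local minimum on the normalized grid
            i = np.argmin(np.abs(grid_pct - true_pct))
            lo, hi = max(i - 3, 0), min(i + 4, 101)
            j = lo + np.argmin(s.normalized[lo:hi])
            assert abs(grid_pct[j] - true_pct) <= 1.0
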