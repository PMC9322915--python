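"""Preprocessing: magnitude, zero-lag filtering, residual analysis,
Fourier-method reconstruction, resampling."""

import numpy as np
import pytest

from gaitagree import signal as sg


def make_stream(t, x, y=None, z=None, rate=None):
    y = np.zeros_like(t) if y is None else y
    z = np.zeros_like(t) if z is None else z
    return sg.AccelStream(t, {"x": np.asarray(x, dtype=float),
                              "y": y, "z": z}, nominal_rate=rate)


class TestVectorMagnitude:
    @pytest.mark.parametrize("vec,expect", [
        ((0.0, 0.0, 0.0), 0.0),
        ((-1.0, 0.0, 0.0), 1.0),
        ((0.3, 0.4, 1.2), 1.3),
    ])
    def test_known_magnitudes(self, vec, expect):
        t = np.arange(5) / 10.0
        stream = sg.AccelStream(t, {"x": np.full(5, vec[0]),
                                    "y": np.full(5, vec[1]),
                                    "z": np.full(5, vec[2])})
        out = sg.vector_magnitude(stream)
        assert np.allclose(out["n"], expect)
        assert np.array_equal(out["x"], stream["x"])  # axes untouched

    def test_missing_channel_rejected(self):
        t = np.arange(5) / 10.0
        stream = sg.AccelStream(t, {"x": np.zeros(5), "y": np.zeros(5)})
        with pytest.raises(sg.SignalError):
            sg.vector_magnitude(stream)


class TestButterworthZeroLag:
    fs = 60.0

    def sine_stream(self, freq, n=1200):
        t = np.arange(n) / self.fs
        return make_stream(t, np.sin(2 * np.pi * freq * t)), t

    def test_dc_gain_unity(self):
        t = np.arange(600) / self.fs
        stream = make_stream(t, np.full(600, 0.7))
        out = sg.butterworth_zero_lag(stream, 4.0)
        assert np.max(np.abs(out["x"] - 0.7)) < 1e-9

    def test_passband_amplitude_matches_two_pass_response(self):
        stream, t = self.sine_stream(1.0)
        out = sg.butterworth_zero_lag(stream, 4.0, order=4)
        # analytic |H|^2 of a 4th-order Butterworth applied twice
        gain = 1.0 / (1.0 + (1.0 / 4.0) ** 8)
        mid = slice(300, 900)
        measured = np.max(np.abs(out["x"][mid]))
        assert measured == pytest.approx(gain, rel=0.01)

    def test_stopband_attenuation(self):
        stream, _ = self.sine_stream(10.0)
        out = sg.butterworth_zero_lag(stream, 4.0, order=4)
        assert np.max(np.abs(out["x"][300:900])) < 0.05

    def test_zero_phase_no_group_delay(self):
        stream, _ = self.sine_stream(1.0)
        out = sg.butterworth_zero_lag(stream, 4.0)
        raw, filt = stream["x"], out["x"]
        corr = np.correlate(filt - filt.mean(), raw - raw.mean(), "full")
        assert int(np.argmax(corr)) == raw.size - 1  # peak at lag 0

    def test_net_design_halves_order(self):
        stream, _ = self.sine_stream(5.0)
        sharp = sg.butterworth_zero_lag(stream, 4.0, order=4)
        soft = sg.butterworth_zero_lag(stream, 4.0, order=4, design="net")
        assert np.max(np.abs(soft["x"][300:900])) \
            > np.max(np.abs(sharp["x"][300:900]))

    def test_cutoff_and_length_guards(self):
        stream, _ = self.sine_stream(1.0)
        with pytest.raises(sg.SignalError):
            sg.butterworth_zero_lag(stream, 30.0)
        short = make_stream(np.arange(10) / self.fs, np.zeros(10))
        with pytest.raises(sg.SignalError):
            sg.butterworth_zero_lag(short, 4.0)


class TestResidualAnalysis:
    fs = 60.0

    def test_white_noise_intercept_recovers_noise_rms(self):
        rng = np.random.default_rng(42)
        n = 10000
        t = np.arange(n) / self.fs
        stream = make_stream(t, 0.1 * rng.standard_normal(n))
        curve = sg.residual_analysis(stream, np.linspace(1, 28, 24),
                                     channels=("x",))
        assert curve.noise_intercept == pytest.approx(0.1, rel=0.15)

    def test_noiseless_sinusoid_passband_residuals_tiny(self):
        t = np.arange(6000) / self.fs
        x = np.sin(2 * np.pi * t)
        stream = make_stream(t, x)
        curve = sg.residual_analysis(stream, np.linspace(2, 28, 14),
                                     channels=("x",))
        assert np.all(curve.residual_rms < 0.01 * np.sqrt(0.5))

    def test_selected_cutoff_brackets_signal_band(self):
        rng = np.random.default_rng(7)
        n = 10000
        t = np.arange(n) / self.fs
        x = np.sin(2 * np.pi * t) + 0.1 * rng.standard_normal(n)
        stream = make_stream(t, x)
        curve = sg.residual_analysis(stream, np.linspace(0.5, 28, 40),
                                     channels=("x",))
        assert 1.0 <= curve.selected_cutoff <= 6.0

    def test_small_grid_rejected(self):
        t = np.arange(600) / self.fs
        stream = make_stream(t, np.sin(2 * np.pi * t))
        with pytest.raises(sg.SignalError):
            sg.residual_analysis(stream, [2.0, 4.0, 6.0])


class TestFourierReconstruction:
    def test_in_basis_signal_recovered_exactly(self):
        f = 0.92
        t = np.arange(0, 12, 1 / 12.5)
        y = -1.0 + 0.4 * np.cos(2 * np.pi * f * t)
        fit = sg.fit_harmonics(t, y, f, n_harmonics=3)
        rng = np.random.default_rng(0)
        probe = rng.uniform(t[0], t[-1], 1000)
        expect = -1.0 + 0.4 * np.cos(2 * np.pi * f * probe)
        assert np.max(np.abs(fit(probe) - expect)) < 1e-6

    def test_constant_stream_reconstructs_constant(self):
        t = np.arange(0, 10, 1 / 12.5)
        fit = sg.fit_harmonics(t, np.full(t.size, 0.3), 0.9, 2)
        assert np.allclose(fit(np.linspace(0, 9, 50)), 0.3, atol=1e-9)

    def test_three_harmonic_waveform_below_nyquist_recovered(self):
        f = 0.92  # 3rd harmonic at 2.76 Hz < 12.5/2
        t = np.arange(0, 13, 1 / 12.5)
        w = 2 * np.pi * f
        y = (-1 + 0.3 * np.cos(w * t) + 0.15 * np.sin(2 * w * t)
             + 0.08 * np.cos(3 * w * t))
        fit = sg.fit_harmonics(t, y, f, n_harmonics=3)
        probe = np.linspace(t[0], t[-1], 2000)
        expect = (-1 + 0.3 * np.cos(w * probe) + 0.15 * np.sin(2 * w * probe)
                  + 0.08 * np.cos(3 * w * probe))
        assert np.sqrt(np.mean((fit(probe) - expect) ** 2)) < 1e-6

    def test_nyquist_and_rank_guards(self):
        t = np.arange(0, 10, 1 / 12.5)
        y = np.sin(2 * np.pi * 0.9 * t)
        with pytest.raises(sg.SignalError):
            sg.fit_harmonics(t, y, 0.9, n_harmonics=7)  # 6.3 Hz > Nyquist
        with pytest.raises(sg.SignalError):
            sg.fit_harmonics(t[:5], y[:5], 0.9, n_harmonics=3)

    def test_reconstruction_consistency_fixed_point(self):
        f = 0.92
        t = np.arange(0, 12, 1 / 12.5)
        rng = np.random.default_rng(3)
        w = 2 * np.pi * f
        y = 0.3 * np.cos(w * t) + 0.1 * np.sin(2 * w * t) \
            + 0.01 * rng.standard_normal(t.size)
        first = sg.fit_harmonics(t, y, f, 3)
        t2, y2 = sg.resample(first, 12.5, t[0], t[-1])
        second = sg.fit_harmonics(t2, y2, f, 3)
        assert abs(first.a0 - second.a0) < 1e-8
        assert np.max(np.abs(first.a - second.a)) < 1e-8
        assert np.max(np.abs(first.b - second.b)) < 1e-8

    def test_stream_level_reconstruction_with_refinement(self):
        from gaitagree import simulate as sim
        cfg = sim.SimulationConfig(cycle_jitter_sd=0.0,
                                   amplitude_jitter_sd=0.0, seed=4)
        sparse, _, truth = sim.make_paired_trial(
            cfg, sim.SensorModel(12.5, clip_range=16.0),
            sim.SensorModel(60.0, clip_range=16.0))
        # start from a deliberately quantized stride estimate
        rough = 1.0 / (round(cfg.stride_period * 12.5) / 12.5)
        rec = sg.fourier_reconstruct(sparse, rough, n_harmonics=6,
                                     refine=True)
        probe = np.linspace(1.0, sparse.time[-1] - 1.0, 1500)
        err = rec["x"](probe) - truth.motion["x"](probe)
        assert np.sqrt(np.mean(err ** 2)) < 1e-5


class TestResample:
    def test_half_open_grid_arithmetic(self):
        const = sg.HarmonicSeries(1.0, 0.5, [0.0], [0.0], 0.0, 2.0)
        t, y = sg.resample(const, 60.0, 0.0, 1.0)
        assert t.size == 60 and np.allclose(y, 0.5)

    def test_out_of_domain_window_rejected(self):
        sig = sg.HarmonicSeries(1.0, 0.0, [1.0], [0.0], 0.0, 2.0)
        with pytest.raises(sg.SignalError):
            sig(np.array([2.5]))

    def test_spline_passes_through_samples(self):
        rng = np.random.default_rng(5)
        t = np.arange(50) / 12.5
        y = rng.standard_normal(50)
        spline = sg.SplineSignal(t, y)
        assert np.allclose(spline(t), y, atol=1e-12)
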