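"""Waveform chain: outlier rule, resampling, spectral steps, delta-t."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocupulse import waveform
from ocupulse.datatypes import ThicknessWaveform
from ocupulse.waveform import (
    WaveformConfig,
    bandpass_filter,
    estimate_heart_rate,
    extract_delta_t,
    mean_peak_to_valley,
    remove_outliers_mad,
    resample_uniform,
)


def _raw(times, values):
    return ThicknessWaveform(stage="raw", times_s=times, cht_um=values)


def _uniform(values, rate=50.0, t0=0.0):
    t = t0 + np.arange(len(values)) / rate
    return ThicknessWaveform(
        stage="uniform", times_s=t, cht_um=values, sample_rate_hz=rate
    )


class TestOutlierRemoval:
    def test_three_mad_rule_worked_example(self):
        # median 10, MAD 0.5, scaled MAD 0.7413, threshold 2.224: only 50 out
        wf = _raw(np.arange(6.0), [10, 10, 11, 9, 10, 50])
        out = remove_outliers_mad(wf)
        assert out.cht_um.tolist() == [10, 10, 11, 9, 10]
        assert out.times_s.tolist() == [0, 1, 2, 3, 4]

    def test_constant_series_kept_by_zero_mad_guard(self):
        wf = _raw(np.arange(8.0), np.full(8, 5.0))
        out = remove_outliers_mad(wf)
        assert out.cht_um.size == 8

    def test_no_outliers_is_identity(self):
        vals = np.array([10.0, 10.5, 9.5, 10.2, 9.8, 10.1])
        out = remove_outliers_mad(_raw(np.arange(6.0), vals))
        assert np.array_equal(out.cht_um, vals)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers_mad(_raw(np.arange(4.0), np.arange(4.0)))


class TestResample:
    def test_already_uniform_nearly_unchanged(self):
        t = np.arange(0, 6, 0.02)
        x = 5 * np.sin(2 * np.pi * 1.2 * t)
        out = resample_uniform(_raw(t, x), target_rate_hz=50.0)
        assert out.sample_rate_hz == 50.0
        resid = np.abs(out.cht_um - 5 * np.sin(2 * np.pi * 1.2 * out.times_s))
        assert resid.max() <= 0.01 * 5

    def test_jittered_sinusoid_amplitude_recovered(self, rng):
        mean_gap = 1 / 30.0
        gaps = mean_gap * (1 + 0.2 * (2 * rng.random(200) - 1))
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        x = 5 * np.sin(2 * np.pi * 1.2 * t)
        out = resample_uniform(_raw(t, x), target_rate_hz=50.0)
        # compare on the interior (interpolation edges excluded)
        sl = slice(10, -10)
        ref = 5 * np.sin(2 * np.pi * 1.2 * out.times_s[sl])
        amp_err = np.abs(out.cht_um[sl] - ref).max()
        assert amp_err <= 0.02 * 5 * 2  # 2% amplitude + interpolation ripple

    def test_zero_net_delay_preserves_peak_time(self):
        t = np.arange(0, 6, 0.02)
        x = np.exp(-0.5 * ((t - 3.0) / 0.3) ** 2)
        out = resample_uniform(_raw(t, x), target_rate_hz=50.0)
        peak_t = out.times_s[np.argmax(out.cht_um)]
        assert abs(peak_t - 3.0) <= 1.0 / 50.0

    def test_sub_nyquist_target_rejected(self):
        t = np.arange(0, 4, 0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            resample_uniform(_raw(t, np.sin(t)), target_rate_hz=10.0,
                             band_upper_hz=6.0)


class TestHeartRate:
    def test_pure_sinusoid(self):
        t = np.arange(0, 6, 0.02)
        wf = _uniform(4 * np.sin(2 * np.pi * 1.2 * t))
        hr = estimate_heart_rate(wf)
        assert hr == pytest.approx(1.2, abs=50.0 / (8 * t.size))

    def test_linear_drift_removed(self):
        t = np.arange(0, 6, 0.02)
        wf = _uniform(4 * np.sin(2 * np.pi * 1.2 * t) + 10 * t)
        assert estimate_heart_rate(wf) == pytest.approx(1.2, abs=0.05)

    def test_white_noise_raises(self, rng):
        wf = _uniform(rng.standard_normal(300))
        with pytest.raises(ValueError, match="dominant"):
            estimate_heart_rate(wf)


class TestBandpass:
    def test_multitone_isolates_cardiac_band(self):
        # 20 s window at 80 Hz: every tone is an integer number of cycles
        rate = 80.0
        t = np.arange(0, 20, 1 / rate)
        cardiac = 5 * np.sin(2 * np.pi * 1.2 * t)
        drift = 20 * np.sin(2 * np.pi * 0.05 * t)
        hf = 3 * np.sin(2 * np.pi * 30.0 * t)
        out = bandpass_filter(
            _uniform(cardiac + drift + hf, rate=rate), heart_rate_hz=1.2
        )
        # residual at the rejected tones, measured by projection
        for f in (0.05, 30.0):
            c = np.abs(np.vdot(np.exp(-2j * np.pi * f * t), out.cht_um)) * 2 / t.size
            assert c <= 0.01 * 5
        assert np.abs(out.cht_um - cardiac).max() <= 0.02 * 5

    def test_peak_to_valley_unbiased_under_offbin_drift(self):
        # physiological drift (fraction of a cycle, amplitude below the
        # pulse) must not bias the recovered peak-to-valley by > 10%
        t = np.arange(0, 4, 0.04)
        x = 300 + 5 * np.sin(2 * np.pi * 1.2 * t) + 3 * np.sin(2 * np.pi * 0.1 * t)
        out = bandpass_filter(_uniform(x, rate=25.0), heart_rate_hz=1.2)
        assert mean_peak_to_valley(out) == pytest.approx(10.0, rel=0.10)

    def test_stop_band_annihilated(self):
        t = np.arange(0, 8, 0.02)
        x = 4 * np.sin(2 * np.pi * 10.0 * t)  # 10 Hz vs band 0.6-3.6 Hz
        out = bandpass_filter(_uniform(x), heart_rate_hz=1.2)
        assert np.linalg.norm(out.cht_um) <= 0.01 * np.linalg.norm(x)

    def test_pass_band_identity(self):
        n, rate = 300, 50.0
        k = 12  # bin-aligned in-band tone: 12 cycles over 6 s = 2 Hz
        t = np.arange(n) / rate
        x = 3 * np.sin(2 * np.pi * k / (n / rate) * t / 1.0)
        x = 3 * np.sin(2 * np.pi * (k / (n / rate)) * t)
        out = bandpass_filter(_uniform(x, rate=rate), heart_rate_hz=1.2)
        assert np.abs(out.cht_um - x).max() <= 1e-6 * 3

    def test_dc_removed(self):
        t = np.arange(0, 6, 0.02)
        out = bandpass_filter(
            _uniform(100.0 + 2 * np.sin(2 * np.pi * 1.2 * t)), heart_rate_hz=1.2
        )
        assert abs(out.cht_um.mean()) < 1e-8

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(a=st.floats(0.1, 10), seed=st.integers(0, 100))
    def test_linearity(self, a, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        fx = bandpass_filter(_uniform(x), 1.2).cht_um
        fy = bandpass_filter(_uniform(y), 1.2).cht_um
        fax = bandpass_filter(_uniform(a * x), 1.2).cht_um
        fxy = bandpass_filter(_uniform(x + y), 1.2).cht_um
        assert np.allclose(fax, a * fx, atol=1e-8 * a)
        assert np.allclose(fxy, fx + fy, atol=1e-8)

    def test_band_above_nyquist_rejected(self):
        t = np.arange(0, 6, 0.1)
        wf = _uniform(np.sin(t), rate=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(wf, heart_rate_hz=2.0, hi_mult=3.0)


class TestPeakToValley:
    def test_sinusoid_gives_twice_amplitude(self):
        t = np.arange(0, 6, 0.02)
        wf = _uniform(5 * np.sin(2 * np.pi * 1.2 * t))
        assert mean_peak_to_valley(wf) == pytest.approx(10.0, abs=0.2)

    def test_amplitude_modulated_cycles_averaged(self):
        # three cycles with peak-to-valley 8, 10, 12 -> mean 10
        rate = 100.0
        amps = [4.0, 5.0, 6.0]
        parts = []
        for i, a in enumerate(amps):
            tc = np.arange(0, 1.0, 1 / rate)
            parts.append(a * np.sin(2 * np.pi * 1.0 * tc))
        x = np.concatenate(parts)
        wf = _uniform(x, rate=rate)
        assert mean_peak_to_valley(wf, min_prominence_um=1.0) == pytest.approx(
            10.0, abs=0.3
        )

    def test_constant_signal_raises(self):
        wf = _uniform(np.full(100, 3.0))
        with pytest.raises(ValueError):
            mean_peak_to_valley(wf)


class TestExtractDeltaT:
    def _synthetic_raw(self, rng, true_p2v=10.0, hr=1.2, noise=0.0, n=300,
                       duration=6.0):
        t = np.sort(rng.uniform(0, duration, n))
        t[0] = 0.0
        t = np.unique(t)
        x = 300 + true_p2v / 2 * np.sin(2 * np.pi * hr * t)
        if noise:
            x = x + rng.normal(0, noise, t.size)
        return _raw(t, x)

    def test_noise_free_recovery(self, rng):
        wf = self._synthetic_raw(rng)
        out = extract_delta_t(wf)
        assert out.stage == "filtered"
        assert 9.5 <= out.delta_t_um <= 10.5
        assert out.heart_rate_hz == pytest.approx(1.2, abs=0.1)

    def test_provenance_chain_complete(self, rng):
        out = extract_delta_t(self._synthetic_raw(rng))
        stages = [w.stage for w in out.lineage()]
        assert stages == ["raw", "cleaned", "uniform", "filtered"]

    def test_explicit_heart_rate_consistent_with_estimate(self, rng):
        raw = self._synthetic_raw(rng)
        auto = extract_delta_t(raw)
        manual = extract_delta_t(raw, WaveformConfig(heart_rate_hz=1.2))
        assert manual.delta_t_um == pytest.approx(auto.delta_t_um, rel=0.02)

    def test_time_shift_invariance(self, rng):
        raw = self._synthetic_raw(rng)
        shifted = _raw(raw.times_s + 17.3, raw.cht_um)
        a = extract_delta_t(raw)
        b = extract_delta_t(shifted)
        assert b.heart_rate_hz == pytest.approx(a.heart_rate_hz, rel=1e-6)
        assert b.delta_t_um == pytest.approx(a.delta_t_um, rel=1e-6)

    def test_delta_t_scales_linearly_with_signal(self, rng):
        raw = self._synthetic_raw(rng)
        scaled = _raw(raw.times_s, raw.cht_um * 3.0)
        a = extract_delta_t(raw, WaveformConfig(heart_rate_hz=1.2))
        b = extract_delta_t(scaled, WaveformConfig(heart_rate_hz=1.2))
        assert b.delta_t_um == pytest.approx(3.0 * a.delta_t_um, rel=1e-6)

    def test_stage_errors_are_tagged(self):
        wf = _raw(np.arange(3.0), np.arange(3.0))
        with pytest.raises(ValueError, match=r"\[outliers\]"):
            extract_delta_t(wf)

    def test_noise_monotonicity_of_error(self, rng):
        """Median delta-t error grows with additive noise, small at default."""
        errs = []
        for noise in (0.0, 1.0, 2.5):
            trial = []
            for seed in range(5):
                r = np.random.default_rng(100 + seed)
                wf = self._synthetic_raw(r, noise=noise)
                out = extract_delta_t(wf, WaveformConfig(heart_rate_hz=1.2))
                trial.append(abs(out.delta_t_um - 10.0) / 10.0)
            errs.append(np.median(trial))
        assert errs[0] <= errs[2] + 0.02
        assert errs[-1] <= 0.10
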