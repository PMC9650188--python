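"""Pulse detection, HRV indicators, respiratory rate and desaturations."""

import numpy as np
import pytest

from circawear.nocturnal import (
    PulseSeries,
    band_power,
    detect_desaturations,
    detect_peaks,
    hourly_oxygen,
    respiratory_rate,
    rmssd,
    window_indicators,
    znormalize,
    LF_BAND,
    HF_BAND,
)


def _pulse_train(beat_times, rate=100.0, dur=None):
    """Synthetic cardiac-band signal with one sharp maximum per beat."""
    dur = dur if dur is not None else beat_times[-1] + 1.0
    t = np.arange(0, dur, 1 / rate)
    phase = np.interp(t, beat_times, np.arange(len(beat_times)))
    frac = phase - np.floor(phase)
    return np.sin(2 * np.pi * frac) + 0.3 * np.sin(4 * np.pi * frac + 1.0), t


class TestDetectPeaks:
    def test_regular_train_recovers_spacing(self):
        beats = np.arange(0, 120, 0.8)
        x, _ = _pulse_train(beats)
        pulse = detect_peaks(x, 100.0)
        assert pulse.pp_intervals.size > 100
        np.testing.assert_allclose(pulse.pp_intervals, 800.0, atol=15.0)

    def test_missed_beat_interval_gated(self):
        beats = np.concatenate([np.arange(0, 40, 0.8), np.arange(43.2, 80, 0.8)])
        x, _ = _pulse_train(beats)
        pulse = detect_peaks(x, 100.0)
        assert pulse.n_gated >= 1
        assert (pulse.pp_intervals < 3000).all()

    def test_zero_signal_empty(self):
        pulse = detect_peaks(np.zeros(1000), 100.0)
        assert pulse.peak_times.size == 0
        assert pulse.pp_intervals.size == 0


class TestRMSSD:
    def test_constant_intervals_zero(self):
        assert rmssd([800.0, 800.0, 800.0]) == 0.0

    def test_hand_computation(self):
        # diffs 10, -20, 15 -> sqrt((100+400+225)/3)
        assert rmssd([800, 810, 790, 805]) == pytest.approx(np.sqrt(725 / 3), abs=1e-3)

    def test_constant_step_closed_form(self):
        assert rmssd([700, 710, 720, 730, 740]) == pytest.approx(10.0)

    def test_too_few_intervals_missing(self):
        assert np.isnan(rmssd([800, 810]))

    def test_shift_invariance(self):
        pp = np.array([820.0, 790.0, 845.0, 805.0, 830.0])
        assert rmssd(pp) == pytest.approx(rmssd(pp + 250.0))


class TestBandPower:
    def test_zero_signal(self):
        assert band_power(np.zeros(1200), 4.0, LF_BAND) == 0.0

    def test_hf_tone_parseval(self):
        t = np.arange(0, 300, 0.25)
        x = np.sin(2 * np.pi * 0.3 * t)
        assert band_power(x, 4.0, HF_BAND) == pytest.approx(0.5, rel=0.05)
        assert band_power(x, 4.0, LF_BAND) < 0.025

    def test_lf_tone_parseval(self):
        t = np.arange(0, 300, 0.25)
        x = np.sin(2 * np.pi * 0.1 * t)
        assert band_power(x, 4.0, LF_BAND) == pytest.approx(0.5, rel=0.05)
        assert band_power(x, 4.0, HF_BAND) < 0.025

    def test_mean_invariance(self):
        t = np.arange(0, 300, 0.25)
        x = np.sin(2 * np.pi * 0.3 * t)
        assert band_power(x + 900.0, 4.0, HF_BAND) == pytest.approx(
            band_power(x, 4.0, HF_BAND), rel=1e-9
        )


class TestRespiratoryRate:
    def test_two_source_mixture(self):
        rate = 10.0
        t = np.arange(0, 30, 1 / rate)
        cardiac = np.sin(2 * np.pi * 1.2 * t)
        resp = np.sin(2 * np.pi * 0.25 * t + 0.7)
        ch1 = 1.0 * cardiac + 0.3 * resp
        ch2 = 0.5 * cardiac + 0.9 * resp
        rr = respiratory_rate(np.stack([ch1, ch2], axis=1), rate)
        assert rr == pytest.approx(15.0, abs=1.0)

    def test_pure_resp_tone(self):
        t = np.arange(0, 30, 0.1)
        tone = np.sin(2 * np.pi * 0.2 * t)
        rr = respiratory_rate(np.stack([tone, 0.8 * tone], axis=1), 10.0)
        assert rr == pytest.approx(12.0, abs=0.5)

    def test_cardiac_only_missing(self):
        t = np.arange(0, 30, 0.1)
        tone = np.sin(2 * np.pi * 1.2 * t)
        rr = respiratory_rate(np.stack([tone, 0.7 * tone], axis=1), 10.0)
        assert np.isnan(rr)


class TestWindowIndicators:
    def test_constant_pp_gives_hr_75(self):
        times = np.arange(0, 3600 * 6, 0.8)
        pp = np.full(times.size - 1, 800.0)
        pulse = PulseSeries(times, pp, times[1:])
        df = window_indicators(pulse, None, None)
        assert len(df) == 720
        np.testing.assert_allclose(df.hr.dropna(), 75.0)

    def test_full_night_row_count(self):
        times = np.arange(0, 3600 * 6, 1.0)
        pulse = PulseSeries(times, np.full(times.size - 1, 1000.0), times[1:])
        spo2 = np.full(6 * 3600, 97.0)
        df = window_indicators(pulse, None, spo2)
        assert len(df) == 720
        np.testing.assert_allclose(df.spo2, 97.0)


class TestZNormalize:
    def test_fit_series_itself(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, 500)
        z = znormalize(x, x.mean(), x.std())
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            znormalize(np.ones(5), 1.0, 0.0)


def _trapezoid(base, depth, start, dur, n=3600):
    """SpO2 trace with one trapezoidal dip (25% fall, 50% hold, 25% rise)."""
    x = np.full(n, base, dtype=float)
    fall, hold = 0.25 * dur, 0.5 * dur
    for i in range(int(start), min(n, int(start + dur) + 1)):
        rel = i - start
        if rel < fall:
            x[i] = base - depth * rel / fall
        elif rel < fall + hold:
            x[i] = base - depth
        elif rel <= dur:
            x[i] = base - depth * (dur - rel) / (dur - fall - hold)
    return x


class TestDesaturations:
    def test_constant_no_events_full_band(self):
        x = np.full(6 * 3600, 98.0)
        assert detect_desaturations(x) == []
        hourly = hourly_oxygen(x, [])
        np.testing.assert_allclose(hourly.pct_ge95, 100.0)
        np.testing.assert_allclose(hourly.pct_90_95, 0.0)
        np.testing.assert_allclose(hourly.pct_lt90, 0.0)

    def test_single_trapezoid_event(self):
        x = _trapezoid(97.0, 5.0, start=600, dur=80)
        events = detect_desaturations(x)
        assert len(events) == 1
        assert events[0].depth == pytest.approx(5.0, abs=0.2)
        # analytic boundaries: the trace crosses baseline-4 at t=617 (during
        # the linear fall) and recovers to baseline-2 at t=672
        assert events[0].start_time == pytest.approx(617, abs=1)
        assert events[0].end_time == pytest.approx(672, abs=1)
        assert events[0].duration == pytest.approx(55, abs=2)

    def test_exactly_4_point_dip_is_not_an_event(self):
        x = _trapezoid(97.0, 4.0, start=600, dur=80)
        assert detect_desaturations(x) == []

    def test_multiple_events_counted_per_hour(self):
        x = np.full(2 * 3600, 98.0)
        for s in (300, 1200, 2400, 5000):
            x = np.minimum(x, _trapezoid(98.0, 6.0, start=s, dur=60, n=x.size))
        events = detect_desaturations(x)
        assert len(events) == 4
        hourly = hourly_oxygen(x, events, hours=2)
        assert list(hourly.odi) == [3, 1]
        assert (hourly.od_duration > 0).all()

    def test_band_partition_sums_to_100(self):
        rng = np.random.default_rng(9)
        x = np.clip(rng.normal(94, 3, 6 * 3600), 80, 100)
        hourly = hourly_oxygen(x, [])
        np.testing.assert_allclose(
            hourly.pct_ge95 + hourly.pct_90_95 + hourly.pct_lt90, 100.0
        )
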