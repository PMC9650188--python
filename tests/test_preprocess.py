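"""Screening rules, Butterworth band-pass, and EEMD denoising."""

import numpy as np
import pytest
from scipy import signal as sig

from circawear.preprocess import bandpass_accel, eemd_denoise, emd, screen_record
from circawear.records import RawRecording


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_dc_rejected(self):
        with pytest.warns(UserWarning):
            y = bandpass_accel(np.full(5000, 0.7), rate=25)
        assert np.max(np.abs(y)) < 1e-6 * 0.7

    def test_inband_tone_preserved(self):
        t = np.arange(0, 60, 1 / 25)
        x = np.sin(2 * np.pi * 1.0 * t)
        with pytest.warns(UserWarning):
            y = bandpass_accel(x, rate=25)
        assert _rms(y) == pytest.approx(_rms(x), rel=0.05)

    def test_slow_drift_attenuated(self):
        t = np.arange(0, 600, 1 / 25)
        x = np.sin(2 * np.pi * 0.01 * t)
        with pytest.warns(UserWarning):
            y = bandpass_accel(x, rate=25)
        assert _rms(y) < 0.1 * _rms(x)

    def test_drift_rejection_matches_filter_response_oracle(self):
        """Forward-backward filtering squares the magnitude response, so
        the closed-form |H| at 0.01 Hz bounds the attenuation (> 20 dB)."""
        sos = sig.butter(4, [0.2, 0.45 * 25], btype="bandpass", fs=25, output="sos")
        _, h = sig.sosfreqz(sos, worN=[0.01], fs=25)
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db > 20

    def test_upper_corner_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            bandpass_accel(np.random.default_rng(0).normal(size=1000), rate=25)

    def test_high_rate_no_warning(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            bandpass_accel(np.random.default_rng(0).normal(size=1000), rate=100)

    def test_too_short_input_errors(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass_accel(np.ones(10), rate=100)


class TestEMD:
    def test_completeness(self):
        """IMFs plus residual reconstruct the input exactly."""
        rng = np.random.default_rng(4)
        t = np.arange(0, 30, 1 / 20)
        x = np.sin(2 * np.pi * 1.2 * t) + 0.5 * np.sin(2 * np.pi * 0.25 * t) + 0.1 * rng.normal(size=t.size)
        modes = emd(x)
        np.testing.assert_allclose(np.sum(modes, axis=0), x, atol=1e-8)

    def test_single_tone_lands_in_one_mode(self):
        t = np.arange(0, 30, 1 / 20)
        x = np.sin(2 * np.pi * 1.0 * t)
        modes = emd(x)
        energies = [np.sum(m**2) for m in modes]
        assert energies[0] / np.sum(energies) > 0.95


class TestEEMD:
    def test_zero_input_zero_output(self):
        with pytest.warns(UserWarning):
            out = eemd_denoise(np.zeros(1000), rate=20, n_ensembles=5, seed=0)
        assert (out == 0).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        x = np.sin(2 * np.pi * 1.2 * np.arange(0, 10, 1 / 20)) + rng.normal(size=200)
        a = eemd_denoise(x, rate=20, n_ensembles=10, seed=42)
        b = eemd_denoise(x, rate=20, n_ensembles=10, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_recovers_tone_at_0db_snr(self):
        """1.2 Hz tone in equal-power white noise: cardiac-band EEMD
        reconstruction correlates > 0.9 with the clean tone."""
        rng = np.random.default_rng(12)
        t = np.arange(0, 20, 1 / 50)
        clean = np.sin(2 * np.pi * 1.2 * t)
        noisy = clean + rng.normal(0, _rms(clean), t.size)
        out = eemd_denoise(noisy, rate=50, n_ensembles=50, bands=((0.66, 3.0),), seed=1)
        r = np.corrcoef(out, clean)[0, 1]
        assert r > 0.9

    def test_two_tone_reconstruction_error(self):
        """0.25 Hz + 1.2 Hz two-tone with bands covering both: relative
        RMS reconstruction error < 15%."""
        t = np.arange(0, 40, 1 / 20)
        x = np.sin(2 * np.pi * 1.2 * t) + 0.8 * np.sin(2 * np.pi * 0.25 * t)
        out = eemd_denoise(
            x, rate=20, n_ensembles=30, noise_scale=0.1,
            bands=((0.66, 3.0), (0.1, 0.5)), seed=3,
        )
        rel_err = _rms(out - x) / _rms(x)
        assert rel_err < 0.15

    def test_invalid_band_errors(self):
        with pytest.raises(ValueError):
            eemd_denoise(np.random.default_rng(0).normal(size=100), rate=20, bands=((5, 15),))


def _make_recording(accel=None, ppg=None, spo2=None, accel_start=8.0, night_start=0.0):
    n_acc = int(12 * 3600 * 25)
    n_ppg = int(6 * 3600 * 100)
    n_spo2 = 6 * 3600
    rng = np.random.default_rng(0)
    if accel is None:
        accel = rng.normal(0, 0.1, (n_acc, 3)).astype(np.float32)
        accel[:, 2] += 1.0
    if ppg is None:
        ppg = rng.normal(0, 1, (n_ppg, 2)).astype(np.float32)
    if spo2 is None:
        spo2 = np.full(n_spo2, 97.0, dtype=np.float32) + rng.normal(0, 0.2, n_spo2).astype(np.float32)
    return RawRecording(
        subject_id="s1", day_index=0, accel_day=accel, ppg_night=ppg,
        spo2_night=spo2, accel_start_hour=accel_start, night_start_hour=night_start,
    )


class TestScreening:
    def test_clean_recording_accepted_exact_lengths(self):
        seg = screen_record(_make_recording())
        assert seg.accepted
        assert seg.ppg.shape[0] == 6 * 3600 * 100
        assert seg.spo2.shape[0] == 6 * 3600
        assert seg.accel.shape[0] == 12 * 3600 * 25

    def test_all_zero_ppg_rejected_null(self):
        rec = _make_recording(ppg=np.zeros((6 * 3600 * 100, 2), dtype=np.float32))
        seg = screen_record(rec)
        assert seg.rejection["ppg"] == "null_signal"

    def test_flatline_ppg_rejected(self):
        rec = _make_recording(ppg=np.full((6 * 3600 * 100, 2), 3.3, dtype=np.float32))
        assert screen_record(rec).rejection["ppg"] == "flat_signal"

    def test_partial_night_marked_truncated(self):
        # PPG covering only 01:00-06:00 fails the entry-window rule
        rec = _make_recording(
            ppg=np.random.default_rng(1).normal(size=(5 * 3600 * 100, 2)).astype(np.float32),
            night_start=1.0,
        )
        assert screen_record(rec).rejection["ppg"] == "truncated"

    def test_stream_outside_window(self):
        rec = _make_recording()
        rec.accel_start_hour = 21.0
        assert screen_record(rec).rejection["accel"] == "outside_window"

    def test_screening_is_idempotent(self):
        """Re-screening the cropped output reproduces the same decision."""
        rec = _make_recording()
        seg1 = screen_record(rec)
        rec2 = RawRecording(
            subject_id="s1", day_index=0, accel_day=seg1.accel,
            ppg_night=seg1.ppg, spo2_night=seg1.spo2,
        )
        seg2 = screen_record(rec2)
        assert seg2.accepted
        np.testing.assert_array_equal(seg1.ppg, seg2.ppg)
        np.testing.assert_array_equal(seg1.accel, seg2.accel)
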