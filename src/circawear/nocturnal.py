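"""Nocturnal physiological indicators from cleaned PPG and SpO2.

Per 30-second window over the 00:00-06:00 night, seven indicators are
produced: heart rate (HR), respiratory rate (RR), SpO2, and four pulse-rate
variability measures -- rMSSD from successive pulse-to-pulse (PP) interval
differences, and LF / HF / LF-HF-ratio from band power of the evenly
resampled PP tachogram.  LF power (0.04-0.15 Hz) is not estimable from a
30-s slice, so the spectral indicators are evaluated on a 5-minute trailing
buffer re-evaluated every 30 s, keeping the 30-s output grid.

Oxygen desaturation events follow the ODI4 convention: an event starts when
SpO2 falls by strictly more than 4 percentage points below the running
baseline (maximum over the preceding 120 s), and ends on recovery to within
2 points of that baseline or after a 300-s cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sig

from .preprocess import RESP_BAND

logger = logging.getLogger(__name__)

__all__ = [
    "PulseSeries",
    "DesatEvent",
    "detect_peaks",
    "rmssd",
    "band_power",
    "respiratory_rate",
    "window_indicators",
    "znormalize",
    "detect_desaturations",
    "hourly_oxygen",
    "LF_BAND",
    "HF_BAND",
    "INDICATORS",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Column order of the per-window indicator table.
INDICATORS = ("hr", "rr", "spo2", "rmssd", "lf", "hf", "lf_hf")

#: Physiologic gate on PP intervals, ms.
PP_GATE_MS = (250.0, 3000.0)
#: Refractory period between detected pulse peaks, s.
REFRACTORY_S = 0.3
#: Tachogram resampling rate, Hz.
TACH_RATE = 4.0


@dataclass
class PulseSeries:
    """Detected pulse peaks and physiologically gated PP intervals."""

    peak_times: np.ndarray      # s since window start, strictly increasing
    pp_intervals: np.ndarray    # ms, gated to PP_GATE_MS
    pp_times: np.ndarray        # s, time of the *ending* peak of each interval
    n_gated: int = 0            # intervals removed by the physiologic gate


@dataclass
class DesatEvent:
    start_time: float   # s
    end_time: float     # s
    depth: float        # percentage points below baseline
    duration: float     # s


def detect_peaks(cardiac: np.ndarray, rate: float) -> PulseSeries:
    """Pulse-peak detection on a denoised cardiac-band channel.

    Local maxima above a rolling amplitude threshold (the 60th percentile
    of the signal over 60-s blocks) with a 300 ms refractory period.
    Successive peak spacings outside (250, 3000) ms are discarded and
    counted in ``n_gated``.
    """
    x = np.asarray(cardiac, dtype=float)
    if x.size == 0 or np.all(x == 0):
        empty = np.zeros(0)
        return PulseSeries(empty, empty, empty)
    block = int(60 * rate)
    n_blocks = max(1, int(np.ceil(x.size / block)))
    thresh = np.empty(x.size)
    for b in range(n_blocks):
        seg = x[b * block : (b + 1) * block]
        thresh[b * block : b * block + seg.size] = np.percentile(seg, 60)
    peaks, _ = sig.find_peaks(x, height=thresh, distance=max(1, int(REFRACTORY_S * rate)))
    times = peaks / rate
    if times.size < 2:
        return PulseSeries(times, np.zeros(0), np.zeros(0))
    pp = np.diff(times) * 1000.0
    ok = (pp > PP_GATE_MS[0]) & (pp < PP_GATE_MS[1])
    n_gated = int((~ok).sum())
    if n_gated:
        logger.info("gated %d non-physiologic PP intervals", n_gated)
    return PulseSeries(times, pp[ok], times[1:][ok], n_gated=n_gated)


def rmssd(pp: np.ndarray) -> float:
    """Root mean square of successive PP-interval differences (ms).

    Needs at least 3 intervals (2 successive differences); otherwise NaN.
    """
    pp = np.asarray(pp, dtype=float)
    if pp.size < 3:
        return float("nan")
    d = np.diff(pp)
    return float(np.sqrt(np.mean(d**2)))


def band_power(x: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    """Average power of ``x`` in a frequency band by periodogram integration.

    Equivalent to integrating the one-sided power spectral density over the
    band, so a unit sinusoid inside the band yields ~A^2/2 = 0.5.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        return float("nan")
    n = x.size
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    # one-sided periodogram: power density = 2|X|^2 / (fs * n), bin width fs/n
    psd = 2.0 * spec / (rate * n)
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    f = np.fft.rfftfreq(n, 1.0 / rate)
    df = rate / n
    m = (f >= band[0]) & (f < band[1])
    return float(np.sum(psd[m]) * df)


def _dominant_freq_padded(x: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    """Periodogram peak inside a band, with zero-padding and parabolic
    interpolation for sub-bin resolution.  NaN if no in-band power."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if x.size < 8 or not np.any(x):
        return float("nan")
    nfft = max(4096, 4 * x.size)
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size), nfft)) ** 2
    f = np.fft.rfftfreq(nfft, 1.0 / rate)
    # dominant means globally dominant: the spectral peak itself must lie
    # in the band, not merely some leakage within it
    k = 1 + int(np.argmax(spec[1:]))
    if not (band[0] <= f[k] <= band[1]) or spec[k] <= 0:
        return float("nan")
    # parabolic refinement on log power
    if 0 < k < spec.size - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        a, b, c = np.log(spec[k - 1 : k + 2])
        denom = a - 2 * b + c
        if denom < 0:
            k = k + 0.5 * (a - c) / denom
    return float(k * rate / nfft)


def respiratory_rate(
    ppg_2ch: np.ndarray,
    rate: float,
    resp_band: tuple[float, float] = RESP_BAND,
) -> float:
    """Respiratory rate (breaths/min) from a two-channel PPG window.

    The window is whitened and rotated to maximise non-Gaussianity
    (two-source separation by an excess-kurtosis scan over rotation
    angles); the component whose dominant frequency lies in the
    respiratory band gives RR = 60 x dominant frequency.  If neither
    separated component lands in the band, a band-filtered single channel
    is used as a fallback (logged); if that also fails, NaN.
    """
    x = np.asarray(ppg_2ch, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected (n, 2) PPG window")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / max(1, xc.shape[0] - 1)
    try:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 1e-12, None)
        white = xc @ v @ np.diag(1.0 / np.sqrt(w))
        # whitened components have unit variance, so the excess kurtosis of
        # any rotation is a closed form in the joint 4th moments
        w1, w2 = white[:, 0], white[:, 1]
        m40 = np.mean(w1**4)
        m31 = np.mean(w1**3 * w2)
        m22 = np.mean(w1**2 * w2**2)
        m13 = np.mean(w1 * w2**3)
        m04 = np.mean(w2**4)
        thetas = np.linspace(0, np.pi / 2, 90, endpoint=False)
        c, s_ = np.cos(thetas), np.sin(thetas)

        def _kurt(c, s):
            return (
                c**4 * m40 + 4 * c**3 * s * m31 + 6 * c**2 * s**2 * m22
                + 4 * c * s**3 * m13 + s**4 * m04 - 3.0
            )

        score = _kurt(c, s_) ** 2 + _kurt(-s_, c) ** 2
        theta = thetas[np.argmax(score)]
        r = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        best = white @ r
        for comp in best.T:
            f0 = _dominant_freq_padded(comp, rate, resp_band)
            if np.isfinite(f0):
                return 60.0 * f0
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate covariance
        pass
    logger.info("ICA separation found no respiratory component; band-filter fallback")
    f0 = _dominant_freq_padded(xc[:, 0], rate, resp_band)
    return 60.0 * f0 if np.isfinite(f0) else float("nan")


def _tachogram(pulse: PulseSeries, t0: float, t1: float, fs: float = TACH_RATE):
    """Evenly resampled PP tachogram (ms) on [t0, t1) by linear interpolation."""
    m = (pulse.pp_times >= t0) & (pulse.pp_times < t1)
    if m.sum() < 4:
        return None
    t = np.arange(t0, t1, 1.0 / fs)
    return np.interp(t, pulse.pp_times[m], pulse.pp_intervals[m])


def window_indicators(
    pulse: PulseSeries,
    ppg_2ch: np.ndarray | None,
    spo2: np.ndarray | None,
    ppg_rate: float = 100.0,
    window_s: float = 30.0,
    night_s: float = 6 * 3600.0,
    hrv_buffer_s: float = 300.0,
    resp_decimate: int = 10,
) -> pd.DataFrame:
    """Per-window indicator table over the night: one row per 30-s window.

    HR = 60000 / mean in-window PP (ms); rMSSD from in-window PP
    differences; LF/HF/ratio from the 4 Hz tachogram over a 5-min trailing
    buffer ending at the window; RR from the two-channel PPG slice; SpO2 as
    the in-window mean.  A 6-h night yields 720 rows.  Windows with too few
    data are NaN.
    """
    n_win = int(round(night_s / window_s))
    starts = np.arange(n_win) * window_s
    out = {k: np.full(n_win, np.nan) for k in INDICATORS}

    pp_idx = np.searchsorted(pulse.pp_times, np.append(starts, night_s))
    if ppg_2ch is not None and resp_decimate > 1:
        resp_sig = np.asarray(ppg_2ch, dtype=float)[::resp_decimate]
        resp_rate_hz = ppg_rate / resp_decimate
    elif ppg_2ch is not None:
        resp_sig, resp_rate_hz = np.asarray(ppg_2ch, dtype=float), ppg_rate
    else:
        resp_sig = None

    for i, t0 in enumerate(starts):
        lo, hi = pp_idx[i], pp_idx[i + 1]
        pp_w = pulse.pp_intervals[lo:hi]
        if pp_w.size >= 2:
            out["hr"][i] = 60000.0 / float(np.mean(pp_w))
        out["rmssd"][i] = rmssd(pp_w)
        tach = _tachogram(pulse, max(0.0, t0 + window_s - hrv_buffer_s), t0 + window_s)
        if tach is not None:
            lf = band_power(tach, TACH_RATE, LF_BAND)
            hf = band_power(tach, TACH_RATE, HF_BAND)
            out["lf"][i], out["hf"][i] = lf, hf
            if hf and np.isfinite(hf) and hf > 0:
                out["lf_hf"][i] = lf / hf
        if resp_sig is not None:
            a = int(t0 * resp_rate_hz)
            b = int((t0 + window_s) * resp_rate_hz)
            seg = resp_sig[a:b]
            if seg.shape[0] >= 8:
                out["rr"][i] = respiratory_rate(seg, resp_rate_hz)
        if spo2 is not None:
            s = np.asarray(spo2, dtype=float)[int(t0) : int(t0 + window_s)]
            if s.size:
                out["spo2"][i] = float(np.nanmean(s))
    df = pd.DataFrame(out)
    df.insert(0, "window_start", starts)
    return df


def znormalize(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Z-score with externally supplied fit parameters.

    The (mean, sd) pair must come from the fitting data (for the ML path:
    training folds only) -- this function never refits.
    """
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-normalize with zero or non-finite SD")
    return (np.asarray(values, dtype=float) - mean) / sd


def detect_desaturations(
    spo2_1hz: np.ndarray,
    drop: float = 4.0,
    rebound: float = 2.0,
    baseline_s: int = 120,
    max_event_s: int = 300,
) -> list[DesatEvent]:
    """ODI4-style desaturation events on a 1 Hz SpO2 series.

    Baseline at time t is the running maximum over the preceding
    ``baseline_s`` samples.  An event starts when SpO2 falls strictly more
    than ``drop`` points below baseline; the baseline is frozen at event
    start; the event ends on recovery to within ``rebound`` points of that
    frozen baseline or at the ``max_event_s`` cap.  Depth is the frozen
    baseline minus the event minimum (always > ``drop`` by construction).
    """
    x = np.asarray(spo2_1hz, dtype=float)
    events: list[DesatEvent] = []
    if x.size == 0:
        return events
    i = 1
    n = x.size
    while i < n:
        base = float(np.nanmax(x[max(0, i - baseline_s) : i]))
        if x[i] < base - drop:
            start = i
            j = i
            while j < n and x[j] < base - rebound and (j - start) < max_event_s:
                j += 1
            end = min(j, n - 1)
            depth = base - float(np.nanmin(x[start : max(start + 1, j)]))
            events.append(
                DesatEvent(start_time=float(start), end_time=float(j), depth=depth,
                           duration=float(j - start))
            )
            i = j + 1
        else:
            i += 1
    return events


def hourly_oxygen(
    spo2_1hz: np.ndarray,
    events: list[DesatEvent] | None = None,
    hours: int = 6,
) -> pd.DataFrame:
    """Per-hour oxygen metrics: ODI, mean OD duration, and SpO2 band occupancy.

    ODI counts the events *starting* in each hour; OD duration is their
    mean duration (0 when the hour has no events).  Band occupancy
    percentages partition all in-hour samples into >= 95%, [90, 95) and
    < 90%, so the three columns sum to 100 per hour with data.
    """
    x = np.asarray(spo2_1hz, dtype=float)
    if events is None:
        events = detect_desaturations(x)
    starts = np.array([e.start_time for e in events])
    durations = np.array([e.duration for e in events])
    rows = []
    for h in range(hours):
        seg = x[h * 3600 : (h + 1) * 3600]
        in_hour = (starts >= h * 3600) & (starts < (h + 1) * 3600) if starts.size else np.zeros(0, bool)
        odi = int(in_hour.sum())
        od_dur = float(durations[in_hour].mean()) if odi else 0.0
        if seg.size:
            valid = seg[~np.isnan(seg)]
            n = valid.size
            pct_ge95 = 100.0 * np.sum(valid >= 95) / n if n else np.nan
            pct_90_95 = 100.0 * np.sum((valid >= 90) & (valid < 95)) / n if n else np.nan
            pct_lt90 = 100.0 * np.sum(valid < 90) / n if n else np.nan
        else:
            pct_ge95 = pct_90_95 = pct_lt90 = np.nan
        rows.append(
            {"hour": h, "odi": odi, "od_duration": od_dur,
             "pct_ge95": pct_ge95, "pct_90_95": pct_90_95, "pct_lt90": pct_lt90}
        )
    return pd.DataFrame(rows)
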