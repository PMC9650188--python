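"""Record screening and signal conditioning.

Screening applies explicit, automated rules for the failure modes seen in
field recordings from wrist wearables: null signals (device off / removed),
flatlines (damaged sensor), and streams that do not cover their analysis
window.  Conditioning covers zero-phase Butterworth band-pass filtering of
the acceleration channels and ensemble empirical mode decomposition (EEMD)
denoising of the nocturnal PPG.

EEMD here is noise-assisted EMD: white-noise realisations are added to the
signal, each noisy copy is decomposed into intrinsic mode functions (IMFs)
by cubic-spline sifting, IMFs are averaged across the ensemble, and the
reconstruction keeps the averaged IMFs whose dominant frequency falls in a
physiological band (cardiac and/or respiratory).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sig
from scipy.interpolate import CubicSpline

from .records import (
    CleanSegments,
    RawRecording,
    ACCEL_RATE,
    PPG_RATE,
    SPO2_RATE,
    DAY_START_H,
    DAY_END_H,
    NIGHT_START_H,
    NIGHT_END_H,
)

__all__ = [
    "bandpass_accel",
    "emd",
    "eemd_denoise",
    "screen_record",
    "CARDIAC_BAND",
    "RESP_BAND",
]

#: Cardiac pulse band for an elderly cohort, 40-180 bpm.
CARDIAC_BAND = (0.66, 3.0)
#: Respiratory band, 6-30 breaths/min.
RESP_BAND = (0.1, 0.5)

#: Flatline rule: channel SD below this fraction of full scale.
FLATLINE_SD_FRACTION = 1e-4


def bandpass_accel(
    x: np.ndarray,
    rate: float = ACCEL_RATE,
    low: float = 0.2,
    high: float = 15.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass of an acceleration channel.

    The nominal 15 Hz upper corner exceeds the 12.5 Hz Nyquist limit of a
    25 Hz accelerometer, so the upper corner is clipped to ``0.45 * rate``
    with a warning; the low corner removes gravity and posture drift.
    Applied forward-backward (``sosfiltfilt``) so features stay
    time-aligned across streams.
    """
    x = np.asarray(x, dtype=float)
    high_eff = min(high, 0.45 * rate)
    if high_eff < high:
        warnings.warn(
            f"upper corner clipped from {high} Hz to {high_eff} Hz "
            f"(Nyquist limit at rate {rate} Hz)"
        )
    sos = sig.butter(order, [low, high_eff], btype="bandpass", fs=rate, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"input of length {x.shape[-1]} too short for zero-phase "
            f"filtering (needs > {padlen} samples)"
        )
    return sig.sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# empirical mode decomposition
# ---------------------------------------------------------------------------

def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take the centre)."""
    d = np.diff(x)
    # treat flats by propagating the previous slope sign
    s = np.sign(d)
    nz = s != 0
    if not nz.all() and nz.any():
        idx = np.where(nz, np.arange(s.size), 0)
        np.maximum.accumulate(idx, out=idx)
        s = s[idx]
    ds = np.diff(s)
    maxima = np.flatnonzero(ds < 0) + 1
    minima = np.flatnonzero(ds > 0) + 1
    return maxima, minima


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of the upper/lower cubic-spline envelopes, or None if the
    signal has too few extrema to sift further."""
    n = x.size
    maxima, minima = _extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    # mirror the outermost two extrema about each endpoint to tame the
    # spline at the boundaries
    def _extend(idx, values):
        left_i = 2 * 0 - idx[1::-1][:2]
        right_i = 2 * (n - 1) - idx[-1:-3:-1]
        ext_i = np.concatenate([left_i - 1, idx, right_i + 1])
        ext_v = np.concatenate([values[idx[1::-1][:2]], values[idx], values[idx[-1:-3:-1]]])
        order = np.argsort(ext_i)
        ext_i, ext_v = ext_i[order], ext_v[order]
        keep = np.concatenate([[True], np.diff(ext_i) > 0])
        return ext_i[keep], ext_v[keep]

    mi, mv = _extend(maxima, x)
    ni, nv = _extend(minima, x)
    t = np.arange(n)
    upper = CubicSpline(mi, mv)(t)
    lower = CubicSpline(ni, nv)(t)
    return 0.5 * (upper + lower)


def emd(
    x: np.ndarray,
    max_imfs: int | None = None,
    max_siftings: int = 10,
    sd_stop: float = 0.2,
) -> list[np.ndarray]:
    """Empirical mode decomposition by cubic-spline sifting.

    Returns the list of IMFs followed by the final residual.  Sifting of
    each IMF stops at the Cauchy-type criterion ``sum((h_prev-h)^2) /
    sum(h_prev^2) < sd_stop`` or after ``max_siftings`` passes.
    """
    x = np.asarray(x, dtype=float)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    n_max = max_imfs if max_imfs is not None else max(1, int(np.log2(max(x.size, 4))) - 1)
    for _ in range(n_max):
        h = residual.copy()
        for _ in range(max_siftings):
            m = _envelope_mean(h)
            if m is None:
                break
            h_new = h - m
            denom = float(np.sum(h**2))
            if denom > 0 and float(np.sum((h - h_new) ** 2)) / denom < sd_stop:
                h = h_new
                break
            h = h_new
        if _envelope_mean(residual) is None:
            break
        imfs.append(h)
        residual = residual - h
        maxima, minima = _extrema(residual)
        if maxima.size + minima.size < 3:
            break
    imfs.append(residual)
    return imfs


def _dominant_freq(x: np.ndarray, rate: float) -> float:
    f, p = sig.periodogram(x, fs=rate, detrend="constant")
    if p[1:].sum() <= 0:
        return 0.0
    return float(f[1:][np.argmax(p[1:])])


def eemd_denoise(
    ppg: np.ndarray,
    rate: float = PPG_RATE,
    n_ensembles: int = 100,
    noise_scale: float = 0.2,
    bands: tuple[tuple[float, float], ...] = (CARDIAC_BAND, RESP_BAND),
    seed: int | None = None,
    max_siftings: int = 10,
) -> np.ndarray:
    """EEMD denoising: keep the IMFs whose dominant frequency is physiological.

    White noise of standard deviation ``noise_scale * SD(signal)`` is added
    in each of ``n_ensembles`` realisations; IMFs are averaged across the
    ensemble by index, and the output is the sum of averaged IMFs whose
    periodogram peak falls inside any of ``bands``.  Deterministic for a
    fixed ``seed``.
    """
    x = np.asarray(ppg, dtype=float)
    if not bands:
        raise ValueError("bands must be non-empty")
    for lo, hi in bands:
        if not (0 < lo < hi < rate / 2):
            raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist)")
    sd = float(np.std(x))
    if sd == 0 or x.size < 8:
        warnings.warn("constant or near-empty input; EEMD returns zeros")
        return np.zeros_like(x)
    rng = np.random.default_rng(seed)
    n_imfs = max(2, int(np.log2(x.size)) - 1)
    acc = np.zeros((n_imfs, x.size))
    for _ in range(n_ensembles):
        noisy = x + rng.normal(0.0, noise_scale * sd, x.size)
        modes = emd(noisy, max_imfs=n_imfs, max_siftings=max_siftings)
        for k in range(n_imfs):
            if k < len(modes):
                acc[k] += modes[k]
    acc /= n_ensembles
    out = np.zeros_like(x)
    for k in range(n_imfs):
        f0 = _dominant_freq(acc[k], rate)
        if any(lo <= f0 <= hi for lo, hi in bands):
            out += acc[k]
    return out


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _screen_stream(
    x: np.ndarray,
    rate: float,
    start_hour: float,
    win_start: float,
    win_end: float,
    full_scale: float,
) -> tuple[np.ndarray | None, str | None]:
    """Crop one stream to its window; return (cropped, rejection reason)."""
    x = np.asarray(x)
    n = x.shape[0]
    if n == 0:
        return None, "null_signal"
    end_hour = start_hour + n / (3600.0 * rate)
    if end_hour <= win_start or start_hour >= win_end:
        return None, "outside_window"
    if start_hour > win_start + 1e-9 or end_hour < win_end - 1e-9:
        return None, "truncated"
    i0 = int(round((win_start - start_hour) * 3600 * rate))
    i1 = i0 + int(round((win_end - win_start) * 3600 * rate))
    cropped = x[i0:i1]
    flat = cropped.astype(float)
    zero_or_nan = np.mean((flat == 0) | np.isnan(flat))
    if zero_or_nan > 0.5:
        return None, "null_signal"
    sd = np.nanstd(flat, axis=0)
    if np.all(sd < FLATLINE_SD_FRACTION * full_scale):
        return None, "flat_signal"
    return cropped, None


def screen_record(recording: RawRecording) -> CleanSegments:
    """Screen one subject-day and crop accepted streams to the fixed windows.

    Per stream, in order: (1) coverage of the analysis window (daytime
    08:00-20:00 for acceleration, 00:00-06:00 for PPG/SpO2) -- otherwise
    ``outside_window`` / ``truncated``; (2) more than 50% zero or missing
    samples -> ``null_signal``; (3) SD below the flatline threshold on
    every channel -> ``flat_signal``.  Screening never raises on bad data;
    it records exactly one reason per rejected stream.
    """
    accel, r_accel = _screen_stream(
        recording.accel_day, ACCEL_RATE, recording.accel_start_hour,
        DAY_START_H, DAY_END_H, full_scale=2.0,
    )
    ppg_scale = float(np.nanmax(np.abs(recording.ppg_night))) if recording.ppg_night.size else 1.0
    ppg, r_ppg = _screen_stream(
        recording.ppg_night, PPG_RATE, recording.night_start_hour,
        NIGHT_START_H, NIGHT_END_H, full_scale=max(ppg_scale, 1.0),
    )
    spo2, r_spo2 = _screen_stream(
        recording.spo2_night, SPO2_RATE, recording.night_start_hour,
        NIGHT_START_H, NIGHT_END_H, full_scale=100.0,
    )
    rejection = {}
    for name, reason in (("accel", r_accel), ("ppg", r_ppg), ("spo2", r_spo2)):
        if reason is not None:
            rejection[name] = reason
    return CleanSegments(
        subject_id=recording.subject_id,
        day_index=recording.day_index,
        accel=accel,
        ppg=ppg,
        spo2=spo2,
        rejection=rejection,
    )
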