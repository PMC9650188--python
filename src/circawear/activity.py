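"""Daytime physical-activity features from wrist acceleration.

The chain is: band-passed vertical acceleration -> per-second activity
counts -> per-minute physical activity (PA) -> non-wear masking ->
percentile-based activity states (sedentary / low / median / high) ->
compressed rhythm curves and per-period summaries.

Counts follow the ActiGraph-style mapping: the signal is resampled to
30 Hz and, per 30-sample (1 s) block, the rectified amplitude above a
dead-band is accumulated, clipped, and quantised by a fixed resolution.
The mapping constants are configurable because count scales are
device-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sig

logger = logging.getLogger(__name__)

__all__ = [
    "StateThresholds",
    "MinuteActivity",
    "accel_to_counts",
    "pa_series",
    "detect_nonwear",
    "state_thresholds",
    "classify_states",
    "compress_curve",
    "period_summary",
    "DAYTIME_PERIODS",
    "NIGHT_PERIODS",
    "STATES",
]

STATES = ("sedentary", "low", "median", "high")

#: Daytime summary periods (start hour, end hour), clock time.
DAYTIME_PERIODS = (
    ("08:00-09:00", 8, 9),
    ("09:00-11:00", 9, 11),
    ("11:00-13:00", 11, 13),
    ("13:00-15:00", 13, 15),
    ("15:00-17:00", 15, 17),
    ("17:00-19:00", 17, 19),
    ("19:00-20:00", 19, 20),
)

#: Nocturnal summary periods (start hour, end hour since midnight).
NIGHT_PERIODS = (
    ("00:00-01:00", 0, 1),
    ("01:00-03:00", 1, 3),
    ("03:00-05:00", 3, 5),
    ("05:00-06:00", 5, 6),
)


@dataclass(frozen=True)
class StateThresholds:
    """40th/70th/90th percentile PA cut-points shared by an analysis set."""

    p40: float
    p70: float
    p90: float

    def __post_init__(self):
        if not (self.p40 <= self.p70 <= self.p90):
            raise ValueError("thresholds must satisfy p40 <= p70 <= p90")


@dataclass
class MinuteActivity:
    """Per-minute activity for one record: PA value, wear flag, state label."""

    record_id: str
    pa: np.ndarray  # int counts per minute
    wear: np.ndarray | None = None  # bool
    state: np.ndarray | None = None  # one of STATES where worn, "" elsewhere
    start_hour: float = 8.0

    def minute_hours(self) -> np.ndarray:
        return self.start_hour + np.arange(self.pa.size) / 60.0


def accel_to_counts(
    vertical: np.ndarray,
    rate: float = 25.0,
    deadband: float = 0.05,
    clip_ceiling: float = 2.0,
    resolution: float = 0.01,
    target_rate: int = 30,
) -> np.ndarray:
    """Convert a band-passed vertical acceleration channel to 1-s counts.

    Per second (30 samples at the 30 Hz working rate), each sample's
    rectified amplitude is reduced by ``deadband`` (values at or below the
    dead-band contribute nothing), clipped to ``clip_ceiling``, summed and
    divided by ``resolution`` (g·sample per count), then rounded.
    """
    x = np.asarray(vertical, dtype=float)
    if x.size == 0:
        return np.zeros(0, dtype=np.int64)
    if rate != target_rate:
        frac = Fraction(target_rate / rate).limit_denominator(1000)
        x = sig.resample_poly(x, frac.numerator, frac.denominator)
    n_sec = x.size // target_rate
    if n_sec == 0:
        return np.zeros(0, dtype=np.int64)
    blocks = np.abs(x[: n_sec * target_rate]).reshape(n_sec, target_rate)
    mag = np.clip(blocks - deadband, 0.0, clip_ceiling)
    counts = np.rint(mag.sum(axis=1) / resolution).astype(np.int64)
    return counts


def pa_series(counts: np.ndarray) -> np.ndarray:
    """Per-minute PA: sum of the minute's 60 per-second counts.

    A trailing partial minute is dropped (logged).
    """
    c = np.asarray(counts, dtype=np.int64)
    n_min = c.size // 60
    if c.size % 60:
        logger.info("dropping trailing partial minute (%d s)", c.size % 60)
    if n_min == 0:
        return np.zeros(0, dtype=np.int64)
    return c[: n_min * 60].reshape(n_min, 60).sum(axis=1)


def detect_nonwear(pa: np.ndarray, threshold_minutes: int = 90) -> np.ndarray:
    """Wear mask: maximal zero-PA runs strictly longer than the threshold
    are flagged as non-wear (False); everything else is wear (True)."""
    pa = np.asarray(pa)
    wear = np.ones(pa.size, dtype=bool)
    if pa.size == 0:
        return wear
    is_zero = pa == 0
    # run-length encode the zero mask
    edges = np.flatnonzero(np.diff(is_zero.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [pa.size]])
    for s, e in zip(starts, ends):
        if is_zero[s] and (e - s) > threshold_minutes:
            wear[s:e] = False
    return wear


def state_thresholds(pa_pool: np.ndarray) -> StateThresholds:
    """40/70/90th percentiles (linear interpolation) of pooled wear-minute PA."""
    pool = np.asarray(pa_pool, dtype=float)
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise ValueError("empty PA pool")
    p40, p70, p90 = np.percentile(pool, [40, 70, 90], method="linear")
    return StateThresholds(float(p40), float(p70), float(p90))


def classify_states(
    pa: np.ndarray,
    thresholds: StateThresholds,
    wear: np.ndarray | None = None,
) -> np.ndarray:
    """Assign an activity state to every wear minute.

    Branch order runs from the top: PA >= p90 -> high, then >= p70 ->
    median, then >= p40 -> low, else sedentary.  In the degenerate case of
    an all-equal pool every wear minute is therefore "high".
    Non-wear minutes get the empty string.
    """
    pa = np.asarray(pa, dtype=float)
    out = np.full(pa.size, "", dtype="U9")
    mask = np.ones(pa.size, bool) if wear is None else np.asarray(wear, bool)
    v = pa[mask]
    s = np.where(
        v >= thresholds.p90,
        "high",
        np.where(v >= thresholds.p70, "median", np.where(v >= thresholds.p40, "low", "sedentary")),
    )
    out[mask] = s
    return out


def compress_curve(series: np.ndarray, block: int = 5) -> np.ndarray:
    """Block-median compression: consecutive non-overlapping blocks reduced
    to their median; a trailing partial block is reduced to its own median.
    720 points with block 5 compress to 144 points."""
    if block < 1:
        raise ValueError("block must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    n_full = x.size // block
    out = []
    if n_full:
        out.append(np.nanmedian(x[: n_full * block].reshape(n_full, block), axis=1))
    if x.size % block:
        out.append([np.nanmedian(x[n_full * block :])])
    return np.concatenate(out)


def period_summary(
    values: np.ndarray,
    hours: np.ndarray,
    periods=DAYTIME_PERIODS,
    normalize: bool = False,
) -> dict[str, float]:
    """Mean of a rhythm curve within each labelled clock period.

    With ``normalize=True`` the curve is min-max scaled to [0, 1] per
    record before averaging, so records with different absolute activity
    scales become comparable.  A period with no finite data yields NaN
    (logged).
    """
    v = np.asarray(values, dtype=float)
    h = np.asarray(hours, dtype=float)
    if v.shape != h.shape:
        raise ValueError("values and hours must align")
    if normalize:
        finite = v[np.isfinite(v)]
        if finite.size and finite.max() > finite.min():
            v = (v - finite.min()) / (finite.max() - finite.min())
        else:
            v = np.zeros_like(v)
    out: dict[str, float] = {}
    for label, start, end in periods:
        m = (h >= start) & (h < end) & np.isfinite(v)
        if not m.any():
            logger.info("period %s has no data", label)
            out[label] = float("nan")
        else:
            out[label] = float(v[m].mean())
    return out
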