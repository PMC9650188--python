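"""Seeded synthetic cohorts of wrist-wearable recordings.

Generates multi-day recordings (daytime 25 Hz tri-axial acceleration,
nocturnal 100 Hz dual-channel PPG, 1 Hz SpO2) for an MCI arm and a control
arm, carrying the group contrasts the downstream analysis is designed to
detect:

* the nocturnal HRV modulation of controls follows a smooth curve peaking
  near 03:00; in the MCI arm that peak is flattened and its phase jittered;
* the LF/HF balance of the MCI arm fluctuates more (larger amplitude
  jitter on the low-frequency modulation);
* the MCI arm has more frequent and deeper oxygen desaturations and a
  lower SpO2 baseline (more time in the 90-95% band and below 90%);
* daytime activity of the MCI arm has a lower high-intensity fraction and
  an excess of low-activity minutes in the morning.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children, so cohorts are byte-identical for
identical arguments.  Desaturation episodes are trapezoids (linear fall,
hold, linear recovery) so event boundaries are analytically known.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import RawRecording, ACCEL_RATE, PPG_RATE

__all__ = [
    "CircadianParams",
    "SubjectProfile",
    "ArtifactSpec",
    "Cohort",
    "generate_cohort",
    "synth_night_ppg",
    "synth_day_accel",
    "inject_artifacts",
    "activity_template",
    "write_cohort",
    "GROUP_DEFAULTS",
]

NIGHT_S = 6 * 3600
DAY_S = 12 * 3600

#: Baseline HF (respiratory-coupled) PP modulation amplitude, ms.  Chosen so
#: the control-arm rMSSD lands in the 70-90 ms range typical of the target
#: population.
HF_BASE_MS = 55.0
#: LF amplitude calibration: linear tachogram interpolation attenuates the
#: HF band more than the LF band, so the generated LF amplitude is shrunk
#: to make the *measured* LF/HF land on the subject's lfhf_mean.
LF_AMP_CAL = 0.78
#: White beat-to-beat PP jitter, ms.
PP_JITTER_MS = 2.0
LF_FREQ_HZ = 0.1


@dataclass(frozen=True)
class CircadianParams:
    """Subject-level physiological parameters driving signal synthesis."""

    mean_hr_bpm: float = 68.0
    hrv_peak_amplitude: float = 55.0   # ms, extra HF modulation at the nocturnal peak
    hrv_peak_hour: float = 3.0         # clock hour of the HRV peak
    lfhf_mean: float = 0.6             # target LF/HF band-power ratio
    lfhf_jitter: float = 0.05          # relative amplitude jitter on the LF modulation
    desat_rate_per_hour: float = 4.0   # Poisson rate of desaturation episodes
    desat_depth_points: float = 5.0    # nominal episode depth, percentage points (> 4)
    high_activity_fraction: float = 0.12   # fraction of vigorous daytime minutes
    morning_low_activity_bias: float = 0.0  # probability a morning minute is damped
    resp_rate_bpm: float = 15.0
    spo2_baseline: float = 98.2        # mean nocturnal SpO2, percent
    spo2_wander: float = 0.5           # SD of slow baseline wander, points

    def validate(self) -> None:
        if self.desat_rate_per_hour < 0:
            raise ValueError("desat_rate_per_hour must be >= 0")
        if not (0 <= self.high_activity_fraction <= 1):
            raise ValueError("high_activity_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str                    # "MCI" or "control"
    n_days: int
    scale_features: dict[str, int]
    circadian_params: CircadianParams

    def __post_init__(self):
        if self.group not in ("MCI", "control"):
            raise ValueError("group must be 'MCI' or 'control'")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        self.circadian_params.validate()


# (mean, sd) of each subject-level parameter draw, per preset and group.
# The "realistic" preset targets the published summary ranges of an elderly
# community cohort (control rMSSD ~70-90 ms, LF/HF ~0.6, ODI ~4-5/h); the
# "separable" preset widens every group gap and shrinks within-group spread
# so planted contrasts dominate sampling noise on small cohorts.
GROUP_DEFAULTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "realistic": {
        "control": {
            "mean_hr_bpm": (68.0, 4.0),
            "hrv_peak_amplitude": (55.0, 10.0),
            "hrv_peak_hour": (3.0, 0.25),
            "lfhf_mean": (0.6, 0.08),
            "lfhf_jitter": (0.05, 0.02),
            "desat_rate_per_hour": (4.0, 1.0),
            "desat_depth_points": (5.0, 0.4),
            "high_activity_fraction": (0.12, 0.02),
            "morning_low_activity_bias": (0.0, 0.0),
            "resp_rate_bpm": (14.8, 1.0),
            "spo2_baseline": (98.2, 0.5),
            "spo2_wander": (0.5, 0.1),
        },
        "MCI": {
            "mean_hr_bpm": (76.0, 5.0),
            "hrv_peak_amplitude": (12.0, 6.0),
            "hrv_peak_hour": (3.0, 0.8),
            "lfhf_mean": (0.6, 0.08),
            "lfhf_jitter": (0.25, 0.08),
            "desat_rate_per_hour": (5.3, 1.2),
            "desat_depth_points": (6.0, 0.6),
            "high_activity_fraction": (0.07, 0.02),
            "morning_low_activity_bias": (0.3, 0.08),
            "resp_rate_bpm": (15.8, 1.2),
            "spo2_baseline": (96.9, 0.9),
            "spo2_wander": (1.0, 0.2),
        },
    },
    "separable": {
        "control": {
            "mean_hr_bpm": (65.0, 2.0),
            "hrv_peak_amplitude": (70.0, 5.0),
            "hrv_peak_hour": (3.0, 0.1),
            "lfhf_mean": (0.6, 0.04),
            "lfhf_jitter": (0.03, 0.01),
            "desat_rate_per_hour": (2.0, 0.5),
            "desat_depth_points": (5.0, 0.3),
            "high_activity_fraction": (0.15, 0.01),
            "morning_low_activity_bias": (0.0, 0.0),
            "resp_rate_bpm": (14.0, 0.5),
            "spo2_baseline": (98.6, 0.2),
            "spo2_wander": (0.3, 0.05),
        },
        "MCI": {
            "mean_hr_bpm": (80.0, 2.0),
            "hrv_peak_amplitude": (4.0, 2.0),
            "hrv_peak_hour": (3.0, 1.0),
            "lfhf_mean": (0.6, 0.04),
            "lfhf_jitter": (0.4, 0.08),
            "desat_rate_per_hour": (8.0, 1.0),
            "desat_depth_points": (7.0, 0.5),
            "high_activity_fraction": (0.05, 0.01),
            "morning_low_activity_bias": (0.5, 0.05),
            "resp_rate_bpm": (17.0, 0.5),
            "spo2_baseline": (95.9, 0.5),
            "spo2_wander": (0.8, 0.1),
        },
    },
}

# scale-feature draw parameters (mean, sd) per group; integers after clipping
_SCALE_DRAWS = {
    "control": {"EDU": (12.0, 3.0), "PSQI": (5.4, 2.8), "SD": (1.06, 0.36),
                "DD": (0.65, 0.66), "CD_lambda": 0.9},
    "MCI": {"EDU": (9.0, 2.5), "PSQI": (7.2, 4.4), "SD": (1.27, 0.59),
            "DD": (1.22, 1.03), "CD_lambda": 1.6},
}
_SCALE_CLIPS = {"EDU": (0, 22), "PSQI": (0, 21), "SD": (0, 3), "DD": (0, 3)}


def _draw_params(group: str, preset: str, rng: np.random.Generator) -> CircadianParams:
    spec = GROUP_DEFAULTS[preset][group]
    vals = {}
    for name, (mu, sd) in spec.items():
        vals[name] = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
    vals["hrv_peak_amplitude"] = max(0.0, vals["hrv_peak_amplitude"])
    vals["lfhf_mean"] = max(0.05, vals["lfhf_mean"])
    vals["lfhf_jitter"] = max(0.0, vals["lfhf_jitter"])
    vals["desat_rate_per_hour"] = max(0.0, vals["desat_rate_per_hour"])
    vals["desat_depth_points"] = max(4.3, vals["desat_depth_points"])
    vals["high_activity_fraction"] = float(np.clip(vals["high_activity_fraction"], 0.0, 1.0))
    vals["morning_low_activity_bias"] = float(np.clip(vals["morning_low_activity_bias"], 0.0, 1.0))
    vals["spo2_baseline"] = float(np.clip(vals["spo2_baseline"], 90.0, 99.2))
    vals["spo2_wander"] = max(0.05, vals["spo2_wander"])
    return CircadianParams(**vals)


def _draw_scales(group: str, rng: np.random.Generator) -> dict[str, int]:
    spec = _SCALE_DRAWS[group]
    out = {}
    for k in ("EDU", "PSQI", "SD", "DD"):
        mu, sd = spec[k]
        lo, hi = _SCALE_CLIPS[k]
        out[k] = int(np.clip(round(rng.normal(mu, sd)), lo, hi))
    out["CD"] = int(rng.poisson(spec["CD_lambda"]))
    return out


# ---------------------------------------------------------------------------
# night synthesis
# ---------------------------------------------------------------------------

def _beat_times(p: CircadianParams, rng: np.random.Generator, t_end: float = NIGHT_S):
    """Pulse onset times with LF/HF-modulated PP intervals; returns
    (beat_times_s, pp_ms at each beat)."""
    base_pp = 60000.0 / p.mean_hr_bpm
    f_resp = p.resp_rate_bpm / 60.0
    phi_lf = rng.uniform(0, 2 * np.pi)
    phi_hf = rng.uniform(0, 2 * np.pi)
    times = [0.0]
    t = 0.0
    # Ornstein-Uhlenbeck state for slow LF amplitude jitter
    ou = 0.0
    tau = 600.0
    while t < t_end:
        h = t / 3600.0
        hf_amp = HF_BASE_MS + p.hrv_peak_amplitude * np.exp(
            -0.5 * ((h - p.hrv_peak_hour) / 1.2) ** 2
        )
        lf_amp = LF_AMP_CAL * np.sqrt(p.lfhf_mean) * hf_amp * np.exp(p.lfhf_jitter * ou)
        pp = (
            base_pp
            + hf_amp * np.sin(2 * np.pi * f_resp * t + phi_hf)
            + lf_amp * np.sin(2 * np.pi * LF_FREQ_HZ * t + phi_lf)
            + PP_JITTER_MS * rng.standard_normal()
        )
        pp = float(np.clip(pp, 320.0, 2200.0))
        dt = pp / 1000.0
        ou += (-ou / tau) * dt + np.sqrt(2.0 * dt / tau) * rng.standard_normal()
        t += dt
        times.append(t)
    return np.asarray(times)


def _desat_schedule(p: CircadianParams, rng: np.random.Generator,
                    t_end: float = NIGHT_S, min_sep: float = 300.0):
    """Poisson desaturation episodes: list of (start_s, duration_s, depth)."""
    n = rng.poisson(p.desat_rate_per_hour * t_end / 3600.0)
    if n == 0:
        return []
    margin = 200.0
    for _ in range(200):
        starts = np.sort(rng.uniform(margin, t_end - margin - 150.0, n))
        if n == 1 or np.all(np.diff(starts) > min_sep):
            break
    else:  # thin overlapping events rather than loop forever
        keep = [starts[0]]
        for s in starts[1:]:
            if s - keep[-1] > min_sep:
                keep.append(s)
        starts = np.asarray(keep)
    events = []
    for s in starts:
        dur = float(rng.uniform(20.0, 120.0))
        depth = float(p.desat_depth_points + rng.uniform(0.0, 1.0))
        events.append((float(s), dur, depth))
    return events


def synth_night_ppg(
    profile: SubjectProfile,
    day_index: int,
    rng: np.random.Generator,
    sensor_noise: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthesize one night of dual-channel PPG and 1 Hz SpO2.

    The cardiac component is a pulse train whose instantaneous rate is
    modulated by a ~0.1 Hz LF oscillation and an HF oscillation coupled to
    the respiratory rate; the respiratory component is mixed into both
    channels with different gains so a two-source separation can recover
    it.  SpO2 is a slowly wandering baseline with trapezoidal desaturation
    episodes.  Returns ``(ppg (n, 2) float32, spo2 (21600,) float32,
    meta)`` where ``meta`` records the planted beats and episodes.
    """
    p = profile.circadian_params
    beats = _beat_times(p, rng)
    t = np.arange(int(NIGHT_S * PPG_RATE)) / PPG_RATE
    phase = np.interp(t, beats, np.arange(beats.size))
    frac = phase - np.floor(phase)
    # one dominant maximum per cycle; the mild 2nd harmonic gives the
    # asymmetric upstroke of a pulse wave without spawning secondary peaks
    cardiac = np.sin(2 * np.pi * frac) + 0.3 * np.sin(4 * np.pi * frac + 1.0)
    cardiac -= cardiac.mean()
    f_resp = p.resp_rate_bpm / 60.0
    resp = np.sin(2 * np.pi * f_resp * t + rng.uniform(0, 2 * np.pi))
    ch1 = 1.0 * cardiac + 0.25 * resp
    ch2 = 0.55 * cardiac + 0.75 * resp
    if sensor_noise > 0:
        ch1 = ch1 + rng.normal(0, sensor_noise, t.size)
        ch2 = ch2 + rng.normal(0, sensor_noise, t.size)
    ppg = np.stack([ch1, ch2], axis=1).astype(np.float32)

    ts = np.arange(NIGHT_S, dtype=float)
    knots = np.arange(0, NIGHT_S + 600, 600)
    wander = np.interp(ts, knots, rng.normal(0, p.spo2_wander, knots.size))
    spo2 = p.spo2_baseline + wander
    events = _desat_schedule(p, rng)
    for start, dur, depth in events:
        fall, hold = 0.25 * dur, 0.5 * dur
        rel = ts - start
        dip = np.zeros_like(ts)
        m1 = (rel >= 0) & (rel < fall)
        dip[m1] = depth * rel[m1] / fall
        m2 = (rel >= fall) & (rel < fall + hold)
        dip[m2] = depth
        m3 = (rel >= fall + hold) & (rel <= dur)
        dip[m3] = depth * (dur - rel[m3]) / (dur - fall - hold)
        spo2 = spo2 - dip
    spo2 = np.clip(spo2, 50.0, 100.0).astype(np.float32)
    meta = {"beat_times": beats, "desat_events": events}
    return ppg, spo2, meta


# ---------------------------------------------------------------------------
# day synthesis
# ---------------------------------------------------------------------------

def activity_template(hours: np.ndarray) -> np.ndarray:
    """Bimodal diurnal intensity template over clock hours 8-20: morning
    peak (08:00-09:00), early-afternoon trough (13:00-14:00), evening
    rebound (17:00-19:00)."""
    h = np.asarray(hours, dtype=float)
    t = (
        0.25
        + 0.75 * np.exp(-0.5 * ((h - 8.5) / 1.0) ** 2)
        + 0.45 * np.exp(-0.5 * ((h - 17.9) / 1.1) ** 2)
        - 0.18 * np.exp(-0.5 * ((h - 13.5) / 0.9) ** 2)
    )
    return np.clip(t, 0.02, None)


def synth_day_accel(
    profile: SubjectProfile,
    day_index: int,
    rng: np.random.Generator,
    intensity_scale: float = 1.0,
    sensor_noise: float = 0.01,
) -> np.ndarray:
    """Synthesize one day (08:00-20:00) of 25 Hz tri-axial acceleration.

    Per-minute intensity follows the diurnal template scaled by the
    subject's parameters; vigorous minutes occur with a probability
    proportional to ``high_activity_fraction`` and morning minutes are
    damped with probability ``morning_low_activity_bias``.  The vertical
    axis carries gravity (1 g) plus a zero-mean oscillation whose envelope
    matches the minute intensity.  ``intensity_scale = 0`` yields a
    constant 1 g vertical channel.
    """
    p = profile.circadian_params
    n_min = DAY_S // 60
    hours = 8.0 + np.arange(n_min) / 60.0
    tmpl = activity_template(hours)
    inten = intensity_scale * 0.35 * tmpl * rng.lognormal(0.0, 0.4, n_min)
    p_vig = np.clip(p.high_activity_fraction * tmpl / tmpl.mean(), 0, 1)
    vig = rng.random(n_min) < p_vig
    inten[vig] *= 3.0
    morning = hours < 11.0
    damped = morning & (rng.random(n_min) < p.morning_low_activity_bias)
    inten[damped] *= 0.2
    inten[rng.random(n_min) < 0.05] = 0.0
    if intensity_scale == 0:
        inten[:] = 0.0

    sps = int(60 * ACCEL_RATE)
    env = np.repeat(inten, sps)
    t = np.arange(n_min * sps) / ACCEL_RATE
    phases = np.repeat(rng.uniform(0, 2 * np.pi, n_min), sps)
    osc = np.sin(2 * np.pi * 1.9 * t + phases)
    noise = rng.normal(0, sensor_noise, t.size) if sensor_noise > 0 else 0.0
    v = 1.0 + env * osc + noise * (env > 0)
    x = 0.35 * env * np.sin(2 * np.pi * 1.9 * t + phases + 1.1)
    y = 0.30 * env * np.sin(2 * np.pi * 0.9 * t + phases + 2.3)
    return np.stack([x, y, v], axis=1).astype(np.float32)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Lazy cohort: profiles are materialised; recordings are generated on
    demand from per-(subject, day) seeds so large cohorts stream."""

    profiles: list[SubjectProfile]
    days_per_subject: int
    seed: int
    preset: str = "realistic"
    sensor_noise: float = 0.05

    def recording(self, subject_index: int, day_index: int) -> RawRecording:
        profile = self.profiles[subject_index]
        ss = np.random.SeedSequence(entropy=self.seed,
                                    spawn_key=(1, subject_index, day_index))
        rng = np.random.default_rng(ss)
        accel = synth_day_accel(profile, day_index, rng, sensor_noise=self.sensor_noise / 5 or 0.0)
        ppg, spo2, meta = synth_night_ppg(profile, day_index, rng,
                                          sensor_noise=self.sensor_noise)
        bed = float(np.clip(rng.normal(22.8, 0.5), 20.5, 23.9))
        wake = float(np.clip(rng.normal(6.8, 0.4), 6.05, 8.0))
        return RawRecording(
            subject_id=profile.subject_id,
            day_index=day_index,
            accel_day=accel,
            ppg_night=ppg,
            spo2_night=spo2,
            diary=(bed, wake),
            meta=meta,
        )

    def iter_recordings(self):
        for i, profile in enumerate(self.profiles):
            for d in range(profile.n_days):
                yield i, self.recording(i, d)

    def __len__(self) -> int:
        return sum(p.n_days for p in self.profiles)


def generate_cohort(
    n_mci: int,
    n_control: int,
    days_per_subject: int,
    seed: int,
    preset: str = "realistic",
    sensor_noise: float = 0.05,
) -> Cohort:
    """Draw subject profiles for both arms and return a lazy cohort.

    Deterministic for fixed arguments.  MCI profiles are drawn with a
    flattened HRV peak, larger LF/HF jitter, higher desaturation rate and
    depth, lower high-activity fraction and a positive morning
    low-activity bias relative to control defaults.
    """
    if n_mci < 0 or n_control < 0:
        raise ValueError("cohort arm sizes must be non-negative")
    if days_per_subject < 1:
        raise ValueError("days_per_subject must be >= 1")
    if preset not in GROUP_DEFAULTS:
        raise ValueError(f"unknown preset {preset!r}")
    profiles: list[SubjectProfile] = []
    for group, count, tag in (("MCI", n_mci, "mci"), ("control", n_control, "ctl")):
        for k in range(count):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(0, 0 if group == "MCI" else 1, k))
            rng = np.random.default_rng(ss)
            profiles.append(
                SubjectProfile(
                    subject_id=f"{tag}_{k:03d}",
                    group=group,
                    n_days=days_per_subject,
                    scale_features=_draw_scales(group, rng),
                    circadian_params=_draw_params(group, preset, rng),
                )
            )
    return Cohort(profiles=profiles, days_per_subject=days_per_subject,
                  seed=seed, preset=preset, sensor_noise=sensor_noise)


def scale_table(cohort: Cohort) -> pd.DataFrame:
    """Per-subject scale-feature table (index: subject_id) with MCI label."""
    rows = []
    for p in cohort.profiles:
        row = {"subject_id": p.subject_id, "label": int(p.group == "MCI")}
        row.update(p.scale_features)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactSpec:
    """One injected artifact: stream in {accel, ppg, spo2}, kind in
    {null_gap, flatline, clipped}, start and duration in seconds."""

    stream: str
    kind: str
    start_s: float
    duration_s: float


_STREAM_RATES = {"accel": ACCEL_RATE, "ppg": PPG_RATE, "spo2": 1.0}


def inject_artifacts(
    recording: RawRecording,
    artifact_spec: list[ArtifactSpec],
    rng: np.random.Generator | None = None,
) -> RawRecording:
    """Return a modified copy of the recording with artifacts applied.

    null_gap zeroes the interval; flatline holds the interval at its mean;
    clipped saturates the interval at half its peak amplitude.  Applied
    intervals are recorded in ``artifacts`` metadata.
    """
    rec = copy.deepcopy(recording)
    for spec in artifact_spec:
        if spec.stream not in _STREAM_RATES:
            raise ValueError(f"unknown stream {spec.stream!r}")
        rate = _STREAM_RATES[spec.stream]
        arr = {"accel": rec.accel_day, "ppg": rec.ppg_night, "spo2": rec.spo2_night}[spec.stream]
        n = arr.shape[0]
        i0 = int(round(spec.start_s * rate))
        i1 = int(round((spec.start_s + spec.duration_s) * rate))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError(
                f"artifact interval [{spec.start_s}, {spec.start_s + spec.duration_s}) s "
                f"outside recording span")
        seg = arr[i0:i1]
        if spec.kind == "null_gap":
            seg[...] = 0.0
        elif spec.kind == "flatline":
            seg[...] = seg.mean(axis=0, keepdims=True) if seg.ndim > 1 else seg.mean()
        elif spec.kind == "clipped":
            ceiling = 0.5 * float(np.max(np.abs(arr))) or 1.0
            np.clip(seg, -ceiling, ceiling, out=seg)
        else:
            raise ValueError(f"unknown artifact kind {spec.kind!r}")
        rec.artifacts.append(spec)
    return rec


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path: str | Path, include_signals: bool = True) -> Path:
    """Write the cohort as one directory per subject.

    Root holds ``manifest.csv`` (subject_id, group, scale features) and
    ``generation.cfg`` (key=value, seeds logged).  Each subject directory
    holds per-day CSV streams with an ISO-8601 timestamp column.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = scale_table(cohort).reset_index()
    manifest.insert(1, "group", [p.group for p in cohort.profiles])
    manifest.to_csv(root / "manifest.csv", index=False)
    cfg = {
        "seed": cohort.seed,
        "preset": cohort.preset,
        "days_per_subject": cohort.days_per_subject,
        "sensor_noise": cohort.sensor_noise,
        "n_subjects": len(cohort.profiles),
    }
    (root / "generation.cfg").write_text(
        "".join(f"{k}={v}\n" for k, v in cfg.items())
    )
    if not include_signals:
        return root
    base = pd.Timestamp("2021-01-01")
    for i, profile in enumerate(cohort.profiles):
        sdir = root / profile.subject_id
        sdir.mkdir(exist_ok=True)
        for d in range(profile.n_days):
            rec = cohort.recording(i, d)
            day0 = base + pd.Timedelta(days=d)
            for name, arr, rate, start_h, cols in (
                ("accel", rec.accel_day, ACCEL_RATE, rec.accel_start_hour, ["ax", "ay", "az"]),
                ("ppg", rec.ppg_night, PPG_RATE, rec.night_start_hour, ["ch1", "ch2"]),
                ("spo2", rec.spo2_night[:, None], 1.0, rec.night_start_hour, ["spo2"]),
            ):
                ts = day0 + pd.to_timedelta(start_h * 3600 + np.arange(arr.shape[0]) / rate, unit="s")
                df = pd.DataFrame(arr, columns=cols)
                df.insert(0, "timestamp", ts.strftime("%Y-%m-%dT%H:%M:%S.%f"))
                df.to_csv(sdir / f"{name}_d{d}.csv", index=False)
    return root
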