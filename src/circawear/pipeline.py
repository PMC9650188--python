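"""End-to-end glue: raw recordings -> indicators -> features -> classification.

`extract_night_indicators` runs screening, cardiac-channel conditioning,
pulse detection and the 30-s indicator grid for one recording;
`cohort_feature_matrix` streams a whole synthetic cohort through it and
assembles the record x 280 feature matrix; `run_classification` applies
feature selection, grid search and pooled LOSO evaluation.

Cardiac conditioning is selectable: ``denoise="bandpass"`` (zero-phase
Butterworth in the cardiac band, the default -- linear-cost, suited to
whole-cohort runs) or ``denoise="eemd"`` (ensemble empirical mode
decomposition, quadratic-cost, suited to short segments and validation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sig

from . import activity as act
from . import features as ft
from . import model as mdl
from . import nocturnal as noct
from .cohort import Cohort, scale_table
from .preprocess import CARDIAC_BAND, bandpass_accel, eemd_denoise, screen_record
from .records import RawRecording, ACCEL_RATE, PPG_RATE

__all__ = [
    "extract_night_indicators",
    "extract_day_activity",
    "cohort_feature_matrix",
    "run_classification",
]


def _cardiac_bandpass(x: np.ndarray, rate: float) -> np.ndarray:
    sos = sig.butter(4, CARDIAC_BAND, btype="bandpass", fs=rate, output="sos")
    return sig.sosfiltfilt(sos, x)


def extract_night_indicators(
    recording: RawRecording,
    denoise: str = "bandpass",
    eemd_kwargs: dict | None = None,
    seed: int = 0,
):
    """Per-30-s indicator table and hourly oxygen metrics for one night.

    Returns ``(indicators, hourly, events)`` or ``None`` if screening
    rejects the night's PPG or SpO2 stream.
    """
    seg = screen_record(recording)
    if "ppg" in seg.rejection or "spo2" in seg.rejection:
        return None
    ppg = np.asarray(seg.ppg, dtype=float)
    if denoise == "bandpass":
        cardiac = _cardiac_bandpass(ppg[:, 0], PPG_RATE)
    elif denoise == "eemd":
        kw = {"bands": (CARDIAC_BAND,), "seed": seed}
        kw.update(eemd_kwargs or {})
        cardiac = eemd_denoise(ppg[:, 0], PPG_RATE, **kw)
    else:
        raise ValueError(f"unknown denoise method {denoise!r}")
    pulse = noct.detect_peaks(cardiac, PPG_RATE)
    indicators = noct.window_indicators(pulse, ppg, seg.spo2, ppg_rate=PPG_RATE)
    events = noct.detect_desaturations(np.asarray(seg.spo2, dtype=float))
    hourly = noct.hourly_oxygen(np.asarray(seg.spo2, dtype=float), events)
    return indicators, hourly, events


def extract_day_activity(recording: RawRecording) -> act.MinuteActivity | None:
    """Daytime counts -> per-minute PA with a non-wear mask for one record."""
    seg = screen_record(recording)
    if "accel" in seg.rejection:
        return None
    vertical = bandpass_accel(np.asarray(seg.accel, dtype=float)[:, 2], ACCEL_RATE)
    counts = act.accel_to_counts(vertical, ACCEL_RATE)
    pa = act.pa_series(counts)
    wear = act.detect_nonwear(pa)
    return act.MinuteActivity(
        record_id=f"{recording.subject_id}_d{recording.day_index}",
        pa=pa,
        wear=wear,
    )


def cohort_feature_matrix(
    cohort: Cohort,
    mode: str = "P",
    denoise: str = "bandpass",
) -> ft.FeatureMatrix:
    """Stream every recording of a cohort into the feature matrix."""
    table = scale_table(cohort)
    if mode == "S":
        return ft.assemble([], scale_table=table, mode="S")
    records = []
    for i, rec in cohort.iter_recordings():
        profile = cohort.profiles[i]
        out = extract_night_indicators(rec, denoise=denoise)
        if out is None:
            continue
        indicators, hourly, _ = out
        records.append(
            {
                "record_id": f"{rec.subject_id}_d{rec.day_index}",
                "subject_id": rec.subject_id,
                "label": int(profile.group == "MCI"),
                "indicators": indicators,
                "hourly": hourly,
            }
        )
    return ft.assemble(records, scale_table=table, mode=mode)


def run_classification(
    fm: ft.FeatureMatrix,
    model_family: str = "gbdt",
    grid: dict | None = None,
    seed: int = 0,
    select: bool = True,
    selection_kwargs: dict | None = None,
) -> tuple[mdl.EvalReport, mdl.SelectionResult | None]:
    """Feature selection (mode P / P+S), grid search and LOSO evaluation.

    Selection runs once on the full matrix before the LOSO loop, mirroring
    the usual sequence for this analysis; pass ``select=False`` to skip it
    (e.g. for mode S, where all 5 scale features enter directly).
    """
    folds = mdl.loso_folds(fm.subject_ids)
    selection = None
    columns = None
    if select and fm.mode in ("P", "P+S"):
        selection = mdl.run_feature_selection(fm, seed=seed, **(selection_kwargs or {}))
        columns = list(selection.retained)
        if fm.mode == "P+S":
            columns += [c for c in ft.SCALE_FEATURES if c in fm.X.columns]
    best, _ = mdl.grid_search(
        model_family, grid or mdl.DEFAULT_GRID, fm, folds, seed=seed, columns=columns
    )
    report = mdl.evaluate(model_family, best, fm, folds, seed=seed, columns=columns)
    return report, selection
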