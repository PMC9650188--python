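"""Record-level feature matrix for MCI classification.

Each record (one subject-night) contributes 280 physiological features in
8 groups: for each of the 7 nocturnal indicator signals (HR, RR, SpO2,
rMSSD, LF, HF, LF/HF) the medians of 36 sliding windows (20-min length,
10-min stride, starting 00:00 ... 05:50, the last window truncated to the
night's end), plus a 28-feature oxygen group (ODI, OD duration, %SpO2>=95
and %SpO2 90-95: six hourly values and the whole-night mean each).
Optionally 5 subjective scale features are joined: education years (EDU),
PSQI total, sleep disturbance (SD), daytime dysfunction (DD), chronic
disease count (CD).

Modes: "P" (physiology only, one row per record), "P+S" (physiology plus
scales), "S" (scales only, exactly one row per subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "sliding_medians",
    "od_feature_group",
    "feature_columns",
    "assemble",
    "SIGNAL_GROUPS",
    "OD_GROUP",
    "SCALE_FEATURES",
]

#: The 7 sliding-median signal groups, in fixed column order.
SIGNAL_GROUPS = ("hr", "rr", "spo2", "rmssd", "lf", "hf", "lf_hf")
OD_GROUP = "od"
ALL_GROUPS = SIGNAL_GROUPS + (OD_GROUP,)

#: Subjective scale features joined in modes S and P+S.
SCALE_FEATURES = ("EDU", "PSQI", "SD", "DD", "CD")

#: OD-group indicator columns of the hourly oxygen table.
_OD_INDICATORS = ("odi", "od_duration", "pct_ge95", "pct_90_95")

N_WINDOWS = 36
WINDOW_MIN = 20
STRIDE_MIN = 10
EPOCH_S = 30
NIGHT_MIN = 360


def sliding_medians(
    series: np.ndarray,
    window_min: int = WINDOW_MIN,
    stride_min: int = STRIDE_MIN,
    epoch_s: int = EPOCH_S,
    night_min: int = NIGHT_MIN,
) -> np.ndarray:
    """Sliding-window medians of one per-epoch indicator series.

    Windows start at 00:00, 00:10, ..., 05:50 (36 starts for the default
    geometry); each window is [start, start + 20 min) intersected with the
    night, so the final window is truncated to 10 min.  The median ignores
    missing samples; an all-missing window yields NaN.
    """
    x = np.asarray(series, dtype=float)
    per_min = 60 // epoch_s
    n_expected = night_min * per_min
    if x.size == 0:
        x = np.full(n_expected, np.nan)
    n_windows = night_min // stride_min
    out = np.full(n_windows, np.nan)
    for k in range(n_windows):
        a = k * stride_min * per_min
        b = min((k * stride_min + window_min) * per_min, n_expected, x.size)
        seg = x[a:b]
        if seg.size and not np.all(np.isnan(seg)):
            out[k] = np.nanmedian(seg)
    return out


def od_feature_group(hourly: pd.DataFrame) -> np.ndarray:
    """28 oxygen features: per indicator (ODI, OD duration, %>=95, %90-95),
    the 6 hourly values plus the whole-night mean of those hourly values."""
    if len(hourly) != 6:
        raise ValueError("expected 6 hourly rows")
    vals = []
    for col in _OD_INDICATORS:
        v = hourly[col].to_numpy(dtype=float)
        vals.extend(v)
        vals.append(float(np.mean(v)))
    return np.asarray(vals)


def feature_columns(mode: str = "P") -> list[str]:
    """Deterministic, order-stable column schema for a given mode."""
    cols: list[str] = []
    if mode in ("P", "P+S"):
        for g in SIGNAL_GROUPS:
            cols.extend(f"{g}_w{k:02d}" for k in range(N_WINDOWS))
        for ind in _OD_INDICATORS:
            cols.extend(f"od_{ind}_h{h}" for h in range(6))
            cols.append(f"od_{ind}_night")
    if mode in ("S", "P+S"):
        cols.extend(SCALE_FEATURES)
    if mode not in ("P", "S", "P+S"):
        raise ValueError(f"unknown mode {mode!r}")
    return cols


def group_of_column(col: str) -> str:
    """Feature-group tag for a column name ('scale' for scale features)."""
    if col in SCALE_FEATURES:
        return "scale"
    if col.startswith("od_"):
        return OD_GROUP
    return col.rsplit("_w", 1)[0]


@dataclass
class FeatureMatrix:
    """Records x features with per-row subject IDs and MCI labels."""

    X: pd.DataFrame
    y: np.ndarray              # 1 = MCI, 0 = control
    subject_ids: np.ndarray
    mode: str
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.group_of:
            self.group_of = {c: group_of_column(c) for c in self.X.columns}

    def columns_in_group(self, group: str) -> list[str]:
        return [c for c, g in self.group_of.items() if g == group]

    @property
    def n_physiological(self) -> int:
        return sum(1 for g in self.group_of.values() if g != "scale")


def assemble(
    records: list[dict],
    scale_table: pd.DataFrame | None = None,
    mode: str = "P",
) -> FeatureMatrix:
    """Assemble the feature matrix from per-record extractions.

    ``records``: each a dict with ``record_id``, ``subject_id``, ``label``
    (1 = MCI), ``indicators`` (per-epoch DataFrame with the 7 indicator
    columns) and ``hourly`` (6-row oxygen table).  ``scale_table`` is
    indexed by subject_id with the 5 scale columns and a ``label`` column
    (required for modes S and P+S).  In mode S exactly one row per subject
    is produced.
    """
    cols = feature_columns(mode)
    if mode == "S":
        if scale_table is None:
            raise ValueError("mode S requires a scale table")
        if scale_table.index.duplicated().any():
            raise ValueError("duplicate subject rows in scale table")
        X = scale_table.loc[:, list(SCALE_FEATURES)].astype(float).copy()
        y = scale_table["label"].to_numpy(dtype=int)
        subjects = scale_table.index.to_numpy()
        X = X.reset_index(drop=True)
        return FeatureMatrix(X=X, y=y, subject_ids=subjects, mode=mode)

    rows, y, subjects, index = [], [], [], []
    for rec in records:
        sid = rec["subject_id"]
        if mode == "P+S":
            if scale_table is None or sid not in scale_table.index:
                raise KeyError(f"record {rec.get('record_id')} maps to unknown subject {sid}")
        vec = []
        ind = rec["indicators"]
        for g in SIGNAL_GROUPS:
            vec.append(sliding_medians(ind[g].to_numpy(dtype=float)))
        vec.append(od_feature_group(rec["hourly"]))
        row = np.concatenate(vec)
        if mode == "P+S":
            row = np.concatenate([row, scale_table.loc[sid, list(SCALE_FEATURES)].to_numpy(dtype=float)])
        rows.append(row)
        y.append(int(rec["label"]))
        subjects.append(sid)
        index.append(rec.get("record_id", f"{sid}_d{len(index)}"))
    X = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return FeatureMatrix(
        X=X,
        y=np.asarray(y, dtype=int),
        subject_ids=np.asarray(subjects, dtype=object),
        mode=mode,
    )
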