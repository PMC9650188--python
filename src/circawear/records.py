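"""Core data containers for one subject-day of wearable recordings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RawRecording", "CleanSegments", "ACCEL_RATE", "PPG_RATE", "SPO2_RATE",
           "DAY_START_H", "DAY_END_H", "NIGHT_START_H", "NIGHT_END_H"]

ACCEL_RATE = 25.0   # Hz, tri-axial wrist acceleration, daytime
PPG_RATE = 100.0    # Hz, dual-channel finger PPG, nocturnal
SPO2_RATE = 1.0     # Hz, oxygen saturation, nocturnal

DAY_START_H, DAY_END_H = 8.0, 20.0      # daytime analysis window (clock hours)
NIGHT_START_H, NIGHT_END_H = 0.0, 6.0   # nocturnal analysis window


@dataclass
class RawRecording:
    """One subject-day: daytime acceleration plus nocturnal PPG and SpO2.

    Streams are stored as plain arrays with a nominal start clock-hour and
    sampling rate; sample ``i`` of a stream occurs at
    ``start_hour + i / (3600 * rate)`` clock hours.
    """

    subject_id: str
    day_index: int
    accel_day: np.ndarray          # (n, 3) g units, ACCEL_RATE
    ppg_night: np.ndarray          # (m, 2) arbitrary units, PPG_RATE
    spo2_night: np.ndarray         # (k,) percent, SPO2_RATE
    diary: tuple[float, float] = (23.0, 7.0)   # (bed clock-hour, wake clock-hour)
    accel_start_hour: float = DAY_START_H
    night_start_hour: float = NIGHT_START_H
    artifacts: list = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.accel_day.ndim != 2 or self.accel_day.shape[1] != 3:
            raise ValueError("accel_day must be (n, 3)")
        if self.ppg_night.ndim != 2 or self.ppg_night.shape[1] != 2:
            raise ValueError("ppg_night must be (m, 2)")
        spo2 = np.asarray(self.spo2_night)
        if spo2.size and (np.nanmin(spo2) < 50 or np.nanmax(spo2) > 100):
            raise ValueError("SpO2 must lie in [50, 100]")


@dataclass
class CleanSegments:
    """Screening result: streams cropped to their fixed analysis windows.

    ``rejection`` maps a stream name (accel / ppg / spo2) to a reason code
    in {null_signal, flat_signal, outside_window, truncated}; accepted
    streams are absent from the map.
    """

    subject_id: str
    day_index: int
    accel: np.ndarray | None
    ppg: np.ndarray | None
    spo2: np.ndarray | None
    rejection: dict[str, str] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return not self.rejection
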