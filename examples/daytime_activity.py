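"""Daytime activity chain: counts -> PA -> non-wear -> states -> rhythm curve.

The band-passed vertical acceleration is converted to per-second activity
counts, summed into per-minute PA, masked for non-wear (zero-PA runs longer
than 90 min), classified into sedentary/low/median/high states by pooled
40/70/90th percentiles, and compressed (block medians of 5) into a rhythm
curve summarised per clock period.
"""

import numpy as np

from circawear import (
    classify_states,
    compress_curve,
    generate_cohort,
    period_summary,
    state_thresholds,
)
from circawear.pipeline import extract_day_activity

cohort = generate_cohort(n_mci=1, n_control=1, days_per_subject=1, seed=12)
activities = [extract_day_activity(cohort.recording(i, 0)) for i in (0, 1)]

pool = np.concatenate([ma.pa[ma.wear] for ma in activities])
thr = state_thresholds(pool)
print(f"pooled state thresholds: p40={thr.p40:.0f} p70={thr.p70:.0f} p90={thr.p90:.0f} counts/min\n")

for ma, profile in zip(activities, cohort.profiles):
    states = classify_states(ma.pa, thr, ma.wear)
    frac_high = np.mean(states[ma.wear] == "high")
    curve = compress_curve(ma.pa.astype(float), block=5)
    hours = 8 + np.arange(ma.pa.size) / 60.0
    means = period_summary(ma.pa.astype(float), hours, normalize=True)
    print(f"{profile.group:>8}: high-activity minutes {100 * frac_high:.1f}%")
    for label in ("08:00-09:00", "13:00-15:00", "17:00-19:00"):
        print(f"          {label} normalized activity {means[label]:.2f}")

print(
    "\nBoth records peak in the morning and trough after lunch; the MCI "
    "record carries fewer high-intensity minutes."
)
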