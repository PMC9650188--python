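"""Synthetic cohort generation: determinism, planted contrasts, artifacts."""

import numpy as np
import pytest

from circawear.activity import detect_nonwear
from circawear.cohort import (
    ArtifactSpec,
    CircadianParams,
    SubjectProfile,
    activity_template,
    generate_cohort,
    inject_artifacts,
    scale_table,
    synth_day_accel,
    synth_night_ppg,
    write_cohort,
)
from circawear.pipeline import extract_day_activity
from circawear.preprocess import screen_record
from circawear.stats import mannwhitney_period


def _profile(group="control", **overrides):
    return SubjectProfile(
        subject_id="t0",
        group=group,
        n_days=1,
        scale_features={"EDU": 12, "PSQI": 5, "SD": 1, "DD": 1, "CD": 0},
        circadian_params=CircadianParams(**overrides),
    )


class TestGenerateCohort:
    def test_empty_cohort(self):
        coh = generate_cohort(0, 0, 5, seed=1)
        assert coh.profiles == []
        assert len(coh) == 0

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            generate_cohort(-1, 5, 3, seed=1)

    def test_seeded_determinism_byte_identical(self):
        a = generate_cohort(2, 1, 2, seed=42)
        b = generate_cohort(2, 1, 2, seed=42)
        assert [p.circadian_params for p in a.profiles] == [p.circadian_params for p in b.profiles]
        assert [p.scale_features for p in a.profiles] == [p.scale_features for p in b.profiles]
        ra, rb = a.recording(0, 1), b.recording(0, 1)
        assert ra.accel_day.tobytes() == rb.accel_day.tobytes()
        assert ra.ppg_night.tobytes() == rb.ppg_night.tobytes()
        assert ra.spo2_night.tobytes() == rb.spo2_night.tobytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(1, 0, 1, seed=1)
        b = generate_cohort(1, 0, 1, seed=2)
        assert a.profiles[0].circadian_params != b.profiles[0].circadian_params

    def test_planted_activity_contrast_in_parameter_draws(self):
        """Monte-Carlo over the generator's own draws: the MCI arm's
        high-activity fraction is stochastically below the control arm's."""
        coh = generate_cohort(30, 30, 7, seed=7)
        mci = [p.circadian_params.high_activity_fraction
               for p in coh.profiles if p.group == "MCI"]
        ctl = [p.circadian_params.high_activity_fraction
               for p in coh.profiles if p.group == "control"]
        assert np.mean(mci) < np.mean(ctl)
        _, _, p = mannwhitney_period(mci, ctl)
        assert p < 0.01

    def test_recording_invariants(self):
        coh = generate_cohort(1, 0, 1, seed=3)
        rec = coh.recording(0, 0)
        rec.validate()
        assert rec.ppg_night.shape == (6 * 3600 * 100, 2)
        assert rec.spo2_night.shape == (6 * 3600,)
        assert rec.accel_day.shape == (12 * 3600 * 25, 3)
        bed, wake = rec.diary
        assert bed < 24.0 and wake > 6.0

    def test_scale_table_columns(self):
        coh = generate_cohort(2, 2, 1, seed=9)
        tab = scale_table(coh)
        assert set(tab.columns) == {"label", "EDU", "PSQI", "SD", "DD", "CD"}
        assert tab.label.sum() == 2


class TestNightSynthesis:
    def test_zero_desat_rate_never_crosses_threshold(self):
        prof = _profile(desat_rate_per_hour=0.0, spo2_wander=0.1)
        _, spo2, meta = synth_night_ppg(prof, 0, np.random.default_rng(0))
        assert meta["desat_events"] == []
        base = prof.circadian_params.spo2_baseline
        assert spo2.min() > base - 4.0

    def test_respiratory_component_frequency(self):
        prof = _profile(resp_rate_bpm=15.0)
        ppg, _, _ = synth_night_ppg(prof, 0, np.random.default_rng(1), sensor_noise=0.0)
        # the respiratory component dominates channel 2 after removing cardiac band
        from circawear.nocturnal import _dominant_freq_padded

        seg = ppg[: 100 * 120, 1].astype(float)
        f0 = _dominant_freq_padded(seg, 100.0, (0.1, 0.5))
        assert f0 == pytest.approx(0.25, abs=0.01)

    def test_planted_events_have_depth_above_4(self):
        prof = _profile(desat_rate_per_hour=6.0)
        _, _, meta = synth_night_ppg(prof, 0, np.random.default_rng(5))
        assert len(meta["desat_events"]) > 0
        assert all(depth > 4.0 for _, _, depth in meta["desat_events"])


class TestDaySynthesis:
    def test_template_shape(self):
        t = activity_template(np.array([8.5, 13.5, 17.9]))
        assert t[1] < t[2] < t[0]

    def test_zero_intensity_gives_pure_gravity(self):
        prof = _profile()
        acc = synth_day_accel(prof, 0, np.random.default_rng(0),
                              intensity_scale=0.0, sensor_noise=0.0)
        np.testing.assert_allclose(acc[:, 2], 1.0, atol=1e-6)
        np.testing.assert_allclose(acc[:, :2], 0.0, atol=1e-6)

    def test_mci_lower_high_intensity_minutes(self):
        """Pooled top-decile minute fraction is lower for MCI day records."""
        coh = generate_cohort(5, 5, 1, seed=17, preset="separable")
        pa_by_group = {"MCI": [], "control": []}
        for i, prof in enumerate(coh.profiles):
            rec = coh.recording(i, 0)
            ma = extract_day_activity(rec)
            pa_by_group[prof.group].append(ma.pa[ma.wear])
        pooled = np.concatenate(pa_by_group["MCI"] + pa_by_group["control"])
        p90 = np.percentile(pooled, 90)
        frac_mci = np.mean(np.concatenate(pa_by_group["MCI"]) >= p90)
        frac_ctl = np.mean(np.concatenate(pa_by_group["control"]) >= p90)
        assert frac_mci < frac_ctl


class TestArtifacts:
    def test_empty_spec_identity(self):
        coh = generate_cohort(1, 0, 1, seed=2)
        rec = coh.recording(0, 0)
        out = inject_artifacts(rec, [])
        np.testing.assert_array_equal(out.accel_day, rec.accel_day)
        assert out.artifacts == []

    def test_out_of_span_errors(self):
        coh = generate_cohort(1, 0, 1, seed=2)
        rec = coh.recording(0, 0)
        with pytest.raises(ValueError, match="outside"):
            inject_artifacts(rec, [ArtifactSpec("spo2", "null_gap", 21000, 1200)])

    def test_null_gap_triggers_nonwear(self):
        coh = generate_cohort(0, 1, 1, seed=4)
        rec = coh.recording(0, 0)
        gap = ArtifactSpec("accel", "null_gap", start_s=2 * 3600, duration_s=100 * 60)
        out = inject_artifacts(rec, [gap])
        ma = extract_day_activity(out)
        nonwear = ~ma.wear
        # the 100-minute null gap appears as >= 91 contiguous non-wear minutes
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate([[0], nonwear, [0]]))).reshape(-1, 2)).ravel()
        assert runs.max() >= 91

    def test_flatline_ppg_rejected_by_screening(self):
        coh = generate_cohort(0, 1, 1, seed=4)
        rec = coh.recording(0, 0)
        flat = ArtifactSpec("ppg", "flatline", start_s=0, duration_s=6 * 3600)
        out = inject_artifacts(rec, [flat])
        seg = screen_record(out)
        assert seg.rejection["ppg"] in ("null_signal", "flat_signal")


def test_write_cohort_manifest_and_config(tmp_path):
    coh = generate_cohort(1, 1, 1, seed=5)
    root = write_cohort(coh, tmp_path / "cohort", include_signals=False)
    manifest = (root / "manifest.csv").read_text().splitlines()
    assert manifest[0].startswith("subject_id,group")
    assert len(manifest) == 3
    cfg = (root / "generation.cfg").read_text()
    assert "seed=5" in cfg
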