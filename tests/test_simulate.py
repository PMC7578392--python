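"""Ground-truth recovery and determinism of the synthetic-dyad generator."""

import numpy as np
import pandas as pd
import pytest

from prosentrain import (
    SimConfig,
    compute_entrainment,
    filter_linguistic,
    study_preset,
    parse_textgrid,
    read_f0_track,
    select_reference_line,
    simulate_cohort,
    simulate_dyad,
    write_f0_track,
    write_metadata,
    write_textgrid,
)
from prosentrain.features import build_dyad_features
from prosentrain.pipeline import cohort_to_dyads, extract_features, score_entrainment
from prosentrain.simulate import InfeasibleDriftError, render_waveform


def measure_dyad(dyad, apply_filter=True):
    tp, tq = dyad.track_participant, dyad.track_partner
    conv = dyad.conversation
    if apply_filter:
        tp = filter_linguistic(tp, conv.participant_tier)
        tq = filter_linguistic(tq, conv.partner_tier)
    feat = build_dyad_features(tp, tq, conv.duration, dyad_id=conv.conversation_id)
    line = select_reference_line(
        dyad.metadata.participant_class, dyad.metadata.partner_class
    )
    return compute_entrainment(feat, line, 1)


def zero_noise_config(**kwargs):
    defaults = dict(
        duration=240.0, frame_noise_sd=0.0, register_sd=0.0,
        celf_effect=0.0, nonspeech_rate=0.0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestGroundTruthRecovery:
    def test_zero_drift_zero_noise_gives_exactly_zero(self):
        cfg = zero_noise_config(drift_delta={"NT": 0.0, "ASD": 0.0})
        res = measure_dyad(simulate_dyad(cfg, "NT", seed=5))
        assert res.delta_ent == pytest.approx(0.0, abs=1e-9)

    def test_programmed_drift_and_split_recovered_exactly(self):
        cfg = zero_noise_config(
            drift_delta={"NT": 5.0, "ASD": -6.0}, responsibility_split=0.4
        )
        dyad = simulate_dyad(cfg, "NT", seed=5)
        res = measure_dyad(dyad)
        assert res.delta_ent == pytest.approx(5.0, abs=1e-9)
        assert (res.resp1, res.resp2) == pytest.approx((0.4, 0.6), abs=1e-9)

    def test_divergence_programmed_negative(self):
        cfg = zero_noise_config(drift_delta={"NT": 5.0, "ASD": -6.0})
        res = measure_dyad(simulate_dyad(cfg, "ASD", seed=9))
        assert res.delta_ent == pytest.approx(-6.0, abs=1e-9)

    def test_teen_boy_dyad_uses_half_matching_line_and_still_recovers(self):
        cfg = zero_noise_config(drift_delta={"NT": 5.0, "ASD": -6.0})
        cov = dict(age=14.5, gender="M", celf_core=105.0,
                   nonverbal_iq=108.0, composite_iq=110.0)
        dyad = simulate_dyad(cfg, "NT", seed=2, covariates=cov)
        assert dyad.metadata.participant_class == "teen_boy"
        assert dyad.truth.line_slope == pytest.approx(2.0)
        res = measure_dyad(dyad)
        assert res.delta_ent == pytest.approx(5.0, abs=1e-9)

    def test_recovery_within_one_hz_at_preset_noise(self):
        cfg = study_preset()
        cfg.n_per_group = 4
        cfg.duration = 300.0
        deltas = {"ASD": [], "NT": []}
        for seed in range(10):
            cfg.seed = seed
            cohort = simulate_cohort(cfg)
            dyads = cohort_to_dyads(cohort)
            feats, _ = extract_features(dyads)
            ent, _ = score_entrainment(dyads, feats)
            truth = cohort.ground_truth_table()
            truth = truth[truth.role == "participant"].set_index("dyad_id")
            merged = ent[ent.k == 1].set_index("dyad_id").join(
                truth[["group", "delta_ent_k1"]]
            )
            for group, part in merged.groupby("group"):
                deltas[group].append((part.delta_ent - part.delta_ent_k1).mean())
        for group in ("ASD", "NT"):
            assert abs(np.mean(deltas[group])) < 1.0

    def test_responsibility_within_tolerance_at_preset_noise(self):
        cfg = study_preset()
        cfg.duration = 300.0
        errors = []
        for seed in range(6):
            dyad = simulate_dyad(cfg, "NT", seed=seed)
            res = measure_dyad(dyad)
            errors.append(abs(res.resp1 - dyad.truth.resp1))
        assert np.mean(errors) < 0.15

    def test_infeasible_drift_raises(self):
        cfg = zero_noise_config(
            drift_delta={"NT": 500.0, "ASD": 0.0},
            registers={"child": 230.0, "teen_girl": 220.0, "teen_boy": 140.0,
                       "adult_female": 200.0, "adult_male": 120.0},
        )
        with pytest.raises(InfeasibleDriftError):
            simulate_dyad(cfg, "NT", seed=1)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(duration=120.0)
        a = simulate_dyad(cfg, "ASD", seed=77)
        b = simulate_dyad(cfg, "ASD", seed=77)
        assert write_textgrid(a.conversation) == write_textgrid(b.conversation)
        assert write_f0_track(a.track_participant) == write_f0_track(b.track_participant)
        assert write_f0_track(a.track_partner) == write_f0_track(b.track_partner)
        assert write_metadata([a.metadata]) == write_metadata([b.metadata])

    def test_different_seeds_differ(self):
        cfg = SimConfig(duration=120.0)
        a = simulate_dyad(cfg, "ASD", seed=77)
        b = simulate_dyad(cfg, "ASD", seed=78)
        assert write_f0_track(a.track_participant) != write_f0_track(b.track_participant)


class TestCohort:
    def test_shape_and_groups(self, small_cohort, small_config):
        groups = [d.metadata.group for d in small_cohort.dyads]
        assert len(small_cohort.dyads) == 2 * small_config.n_per_group
        assert groups.count("ASD") == groups.count("NT") == small_config.n_per_group

    def test_ground_truth_rows_two_per_dyad(self, small_cohort):
        table = small_cohort.ground_truth_table()
        assert len(table) == 2 * len(small_cohort.dyads)
        assert set(table.role) == {"participant", "partner"}

    def test_preset_covariate_calibration(self):
        # sampling-distribution check: cohort CELF means sit within 3 SE of
        # the configured group means over 40 seeds
        cfg = study_preset()
        cfg.duration = 60.0
        celf = {"ASD": [], "NT": []}
        for seed in range(40):
            cfg.seed = 1000 + seed
            for meta in simulate_cohort(cfg).metadata:
                celf[meta.group].append(meta.celf_core)
        for group, (mean, sd) in (("ASD", (88.0, 12.43)), ("NT", (109.0, 11.56))):
            se = sd / np.sqrt(len(celf[group]))
            assert abs(np.mean(celf[group]) - mean) < 3 * se

    def test_preset_drift_signs_and_sizes(self):
        cfg = study_preset()
        assert cfg.n_per_group == 12
        assert cfg.drift_delta["ASD"] < 0 < cfg.drift_delta["NT"]
        assert cfg.celf["ASD"][0] == 88.0 and cfg.celf["NT"][0] == 109.0

    def test_generated_files_parse_cleanly(self, small_cohort, tmp_path, recwarn):
        from prosentrain.simulate import write_cohort

        write_cohort(small_cohort, tmp_path)
        dyad_id = small_cohort.dyads[0].metadata.dyad_id
        conv = parse_textgrid((tmp_path / f"{dyad_id}.TextGrid").read_text())
        track = read_f0_track(tmp_path / f"{dyad_id}_S1.f0.csv")
        assert conv.duration == pytest.approx(small_cohort.config.duration)
        assert track.n_voiced > 0
        assert len(recwarn) == 0


class TestFilteringMatters:
    def test_nonspeech_contamination_biases_unfiltered_pipeline(self):
        cfg = SimConfig(duration=600.0, nonspeech_rate=1.0)
        diffs = []
        for seed in range(8):
            dyad = simulate_dyad(cfg, "ASD", seed=300 + seed)
            filtered = measure_dyad(dyad, apply_filter=True)
            unfiltered = measure_dyad(dyad, apply_filter=False)
            diffs.append(abs(filtered.delta_ent - unfiltered.delta_ent))
        assert np.mean(diffs) > 0.5

    def test_filtering_is_noop_without_contamination(self):
        cfg = SimConfig(duration=240.0, nonspeech_rate=0.0)
        dyad = simulate_dyad(cfg, "ASD", seed=4)
        a = measure_dyad(dyad, apply_filter=True)
        b = measure_dyad(dyad, apply_filter=False)
        assert a.delta_ent == pytest.approx(b.delta_ent, abs=1e-12)


class TestWaveformRendering:
    def test_rendered_waveform_tracks_programmed_f0(self):
        from prosentrain import SpeakerClassRange, estimate_f0

        cfg = zero_noise_config(duration=20.0, drift_delta={"NT": 0.0, "ASD": 0.0})
        dyad = simulate_dyad(cfg, "NT", seed=6)
        rate = 16000
        wave = render_waveform(dyad.track_participant, rate=rate)
        est = estimate_f0(wave, rate, SpeakerClassRange("child", 100.0, 450.0))
        target = dyad.truth.register_participant
        voiced = est.voiced_f0()
        assert len(voiced) > 50
        assert abs(np.median(voiced) - target) / target < 0.02
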