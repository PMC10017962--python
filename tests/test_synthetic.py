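"""Synthetic cohort generator: planting, synthesis, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from robustmark import synthetic as syn
from robustmark.acoustic import contour_std, pause_features
from robustmark.audio import detect_speech_pauses, f0_contour
from robustmark.stats import spearman


class TestEffectPlan:
    def test_unknown_biomarker_rejected(self):
        with pytest.raises(ValueError, match="NOSUCH"):
            syn.EffectPlan("NOSUCH", "SS", "up", 1.0)

    def test_null_direction_requires_zero_magnitude(self):
        with pytest.raises(ValueError):
            syn.EffectPlan("F0STD", "SS", None, 1.0)

    def test_conflicting_directions_on_one_parameter(self):
        with pytest.raises(ValueError, match="conflicting"):
            syn.plant_effects(
                [
                    syn.EffectPlan("SILTIME", "SS", "up", 1.0),
                    syn.EffectPlan("SILPERC", "SS", "down", 1.0),
                ]
            )


class TestPlanting:
    def test_downward_shift_of_group_mean(self):
        model = syn.plant_effects([syn.EffectPlan("F0STD", "SS", "down", 1.0)])
        rng = np.random.default_rng(0)
        cn = [model.draw_subject(f"c{i}", "CN", rng)["SS"].f0_sd for i in range(400)]
        pd_ = [model.draw_subject(f"p{i}", "PD", rng)["SS"].f0_sd for i in range(400)]
        base_mean, base_sd = syn.PARAM_SPECS["f0_sd"][:2]
        assert np.mean(cn) - np.mean(pd_) == pytest.approx(base_sd, abs=0.2 * base_sd)

    def test_null_plan_identical_distributions(self):
        model = syn.plant_effects([])
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        a = model.draw_subject("s", "CN", rng1)["SS"]
        b = model.draw_subject("s", "PD", rng2)["SS"]
        assert a.f0_sd == b.f0_sd
        assert a.pause_rate == b.pause_rate

    def test_severity_link_hits_target_spearman(self):
        # Monte-Carlo over 50 seeds, n = 200 PD subjects each
        model = syn.plant_effects([syn.EffectPlan("SILDUR", "SS", "up", 1.0, 0.6)])
        rhos = []
        for s in range(50):
            rng = np.random.default_rng(s)
            vals, sevs = [], []
            for i in range(200):
                p = model.draw_subject(f"x{i}", "PD", rng)["SS"]
                vals.append(p.pause_log_mean)
                sevs.append(p.updrs3)
            rhos.append(spearman(vals, sevs)[0])
        assert abs(np.mean(rhos) - 0.6) <= 0.1

    def test_severity_absent_for_controls(self):
        model = syn.plant_effects([])
        p = model.draw_subject("s", "CN", np.random.default_rng(0))["SS"]
        assert p.updrs3 is None and p.hy is None

    def test_severity_ranges_for_patients(self):
        model = syn.plant_effects([])
        rng = np.random.default_rng(0)
        for i in range(50):
            p = model.draw_subject(f"s{i}", "PD", rng)["SS"]
            assert 1 <= p.hy <= 5
            assert 0.0 <= p.updrs3_1 <= 4.0


class TestSynthesis:
    def test_no_pauses_means_no_silent_time(self):
        model = syn.plant_effects([])
        p = model.draw_subject("s", "CN", np.random.default_rng(1))["SS"]
        p.pause_rate = 1e-6
        sym = syn.plan_symbolic(p, "SS", 30.0, np.random.default_rng(2))
        w = syn.render_audio(sym)
        seg = detect_speech_pauses(w)
        # only the constant lead/trail edges remain silent
        assert pause_features(seg)["SILTIME"] < 0.8

    def test_flat_pitch_recovered_flat(self):
        model = syn.plant_effects([])
        p = model.draw_subject("s", "CN", np.random.default_rng(3))["SS"]
        p.f0_mean, p.f0_sd = 150.0, 0.0
        sym = syn.plan_symbolic(p, "SS", 20.0, np.random.default_rng(4))
        w = syn.render_audio(sym)
        assert contour_std(f0_contour(w)) < 2.0

    def test_planted_mean_pause_recovered(self):
        # Monte-Carlo over seeds: the mean measured pause duration must sit
        # within 15% of the planted 0.8 s (per-seed noise at ~25 pauses is
        # close to that band on its own)
        model = syn.plant_effects([])
        estimates = []
        for s in range(6):
            p = model.draw_subject("s", "CN", np.random.default_rng(s))["SS"]
            p.pause_log_sd = 0.45
            p.pause_log_mean = math.log(0.8) - 0.45**2 / 2
            p.pause_rate = 0.45
            sym = syn.plan_symbolic(p, "SS", 70.0, np.random.default_rng(100 + s))
            if len(sym.segmentation.durations("pause")) < 20:
                continue
            w = syn.render_audio(sym)
            estimates.append(pause_features(detect_speech_pauses(w))["SILDUR"])
        assert estimates
        assert abs(np.mean(estimates) - 0.8) / 0.8 <= 0.15

    def test_infeasible_pause_configuration_rejected(self):
        model = syn.plant_effects([])
        p = model.draw_subject("s", "CN", np.random.default_rng(5))["SS"]
        p.pause_rate = 0.9
        p.pause_log_mean = math.log(2.0)
        with pytest.raises(ValueError, match="infeasible"):
            syn.plan_symbolic(p, "SS", 30.0, np.random.default_rng(6))

    def test_transcript_times_consistent_with_segmentation(self):
        model = syn.plant_effects([])
        p = model.draw_subject("s", "CN", np.random.default_rng(7))["SS"]
        sym = syn.plan_symbolic(p, "SS", 40.0, np.random.default_rng(8))
        speech = [(s, e) for s, e, lab in sym.segmentation.intervals if lab == "speech"]
        for tok in sym.transcript.tokens:
            assert any(s - 1e-9 <= tok.start and tok.end <= e + 1e-9 for s, e in speech)


class TestGenerateCohort:
    @staticmethod
    def small_config(**kw):
        return syn.CohortConfig(
            datasets=[
                syn.DatasetSpec("A", 2, 2, tasks=("SS",)),
                syn.DatasetSpec("B", 2, 2, tasks=("SS", "RP")),
            ],
            durations={"SS": 6.0, "RP": 5.0, "TDU": 4.0},
            **kw,
        )

    def test_manifest_row_counting(self, tmp_path):
        cfg = syn.CohortConfig(
            datasets=[
                syn.DatasetSpec(f"D{i}", 20, 20) for i in range(6)
            ],
            durations={"SS": 3.0, "RP": 2.5, "TDU": 2.0},
        )
        bundle = syn.generate_cohort(cfg, 9, tmp_path / "c")
        assert len(bundle.manifest) == 6 * 40 * 3  # 720

    def test_same_seed_identical_manifest_and_truth(self, tmp_path):
        cfg = self.small_config()
        b1 = syn.generate_cohort(cfg, 5, tmp_path / "x")
        b2 = syn.generate_cohort(cfg, 5, tmp_path / "y")
        drop = ["audio_path", "transcript_path"]
        assert b1.manifest.drop(columns=drop).equals(b2.manifest.drop(columns=drop))
        assert b1.ground_truth == b2.ground_truth
        # audio bit-identical
        a = (tmp_path / "x" / "A").glob("*.wav")
        for p in sorted(a):
            q = tmp_path / "y" / "A" / p.name
            assert p.read_bytes() == q.read_bytes()

    def test_manifest_paths_resolve(self, tmp_path):
        import os

        bundle = syn.generate_cohort(self.small_config(), 5, tmp_path / "z")
        for rec in bundle.manifest.itertuples():
            assert os.path.exists(rec.audio_path)
            assert os.path.exists(rec.transcript_path)
        assert set(bundle.ground_truth) == set(bundle.manifest["subject_id"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            syn.DatasetSpec("A", 0, 5)


class TestSimulateFeatureTable:
    def test_symbolic_features_match_real_feature_functions(self):
        cfg = syn.CohortConfig(
            datasets=[syn.DatasetSpec("A", 3, 3, tasks=("SS",))],
            durations={"SS": 30.0},
        )
        feats, subjects = syn.simulate_feature_table(cfg, 3)
        wide = feats.pivot_table(index="subject_id", columns="biomarker", values="value")
        # internal consistency of derived pause quantities
        assert np.allclose(
            wide["SILPERC"],
            100 * wide["SILTIME"] / (wide["SPTIME"] + wide["SILTIME"]),
        )
        assert np.allclose(wide["SILSPRAT"], wide["SILTIME"] / wide["SPTIME"])
        assert (wide["NPCNT"] <= wide["NOUNCNT"] + 1e-9).all()
        assert len(subjects) == 6
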