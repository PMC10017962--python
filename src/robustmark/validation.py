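"""Calibration studies: does the pipeline recover what the generator plants?

Three standing experiments, each driven by a single seed:

* :func:`parameter_recovery` — sweep one cohort's generative parameters and
  check that the audio extractors track them (rank correlation between the
  planted value and the measured biomarker across subjects);
* :func:`null_false_rejection` — replicate null cohorts (no planted effects)
  and measure how often a biomarker family produces any FDR rejection;
* :func:`plant_and_recover` — plant the full expected-behavior profile in
  several datasets and measure, per biomarker, how often the adjudicator
  declares it robust across seeds.

The recovery study renders waveforms and runs the real extractors; the two
replicate-heavy studies use the audio-free symbolic route, which exercises
everything downstream of waveform rendering.
"""

from __future__ import annotations

import math

import numpy as np

from . import audio, acoustic, cognitive, pipeline, stats, synthetic

__all__ = [
    "parameter_recovery",
    "null_false_rejection",
    "plant_and_recover",
]


def parameter_recovery(
    n_subjects: int = 100,
    seed: int = 0,
    duration: float = 40.0,
) -> dict[str, float]:
    """Spearman correlation between planted parameters and extracted values.

    Each subject gets independent draws of pitch variability, intensity
    variability, mean pause duration and rhythm jitter over wide plausible
    ranges (other parameters held at the population prototype); one
    spontaneous-speech recording per subject is rendered and the four
    biomarkers are extracted from the waveform (rhythm from the transcript
    anchors plus the detected segmentation, as in the pipeline).
    """
    model = synthetic.plant_effects([])
    rng_master = np.random.default_rng(seed)
    truth = {k: [] for k in ("f0_sd", "intensity_sd", "mean_pause", "rhythm_jitter")}
    est = {k: [] for k in ("F0STD", "INTSTD", "SILDUR", "RHYSTD")}
    for i in range(n_subjects):
        rng = np.random.default_rng([seed, 1, i])
        p = model.draw_subject(f"r{i:03d}", "CN", rng)["SS"]
        f0_sd = rng_master.uniform(5.0, 45.0)
        intensity_sd = rng_master.uniform(1.5, 8.0)
        mean_pause = rng_master.uniform(0.25, 1.0)
        jitter = rng_master.uniform(0.01, 0.25)
        p.f0_sd = f0_sd
        p.intensity_sd = intensity_sd
        p.pause_log_sd = 0.45
        p.pause_log_mean = math.log(mean_pause) - 0.45**2 / 2
        p.rhythm_jitter = jitter
        sym = synthetic.plan_symbolic(p, "SS", duration, rng)
        w = synthetic.render_audio(sym)

        seg = audio.detect_speech_pauses(w)
        f0 = audio.f0_contour(w)
        norm = audio.normalize_loudness(w)
        truth["f0_sd"].append(f0_sd)
        truth["intensity_sd"].append(intensity_sd)
        truth["mean_pause"].append(mean_pause)
        truth["rhythm_jitter"].append(jitter)
        est["F0STD"].append(acoustic.contour_std(f0))
        est["INTSTD"].append(acoustic.contour_std(audio.intensity_contour(norm)))
        est["SILDUR"].append(acoustic.pause_features(seg)["SILDUR"])
        onsets = [s for s, _ in sym.word_times]
        est["RHYSTD"].append(cognitive.rhythm_std_fluent(onsets, segmentation=seg))
    pairs = {
        "f0_sd": "F0STD",
        "intensity_sd": "INTSTD",
        "mean_pause": "SILDUR",
        "rhythm_jitter": "RHYSTD",
    }
    out = {}
    for param, biomarker in pairs.items():
        x = np.asarray(truth[param])
        y = np.asarray(est[biomarker])
        ok = np.isfinite(y)
        rho, _ = stats.spearman(x[ok], y[ok])
        out[param] = rho
    return out


def null_false_rejection(
    n_replicates: int = 200,
    seed: int = 0,
    n_per_group: int = 20,
) -> tuple[float, int]:
    """Fraction of biomarker-family instances with any FDR rejection under
    the null.

    Each replicate is one dataset, spontaneous speech only, with no planted
    effects; within each replicate the three families (acoustic, linguistic,
    cognitive) are corrected separately, as in the analysis.  Returns
    ``(proportion, n_family_instances)``.
    """
    rejections = 0
    instances = 0
    for r in range(n_replicates):
        cfg = synthetic.CohortConfig(
            datasets=[synthetic.DatasetSpec("NULL", n_per_group, n_per_group,
                                            tasks=("SS",))],
            plan=[],
            durations={"SS": 60.0},
        )
        feats, subjects = synthetic.simulate_feature_table(cfg, seed + 1000 + r)
        res = pipeline.run_analyze(feats, subjects=None)
        for _, fam in res.tests.groupby("family"):
            instances += 1
            rejections += int(fam["significant"].any())
    return rejections / instances, instances


def plant_and_recover(
    n_seeds: int = 20,
    seed: int = 0,
    n_per_group: int = 40,
    n_datasets: int = 3,
    magnitude: float = 1.5,
    severity_link: float = 0.5,
) -> dict[str, float]:
    """Per-biomarker fraction of seeds in which it is adjudicated robust.

    Plants the full expected-behavior profile at ``magnitude`` (Cohen's d on
    the generative parameters) with severity links of ``+/-severity_link``
    in ``n_datasets`` datasets of ``n_per_group`` subjects per group, runs
    the analysis and the three-condition adjudication, and tallies verdicts
    per planted biomarker name.
    """
    plan = synthetic.table4_effect_plan(magnitude, severity_link)
    planted = sorted({e.biomarker for e in plan})
    hits = {b: 0 for b in planted}
    for s in range(n_seeds):
        cfg = synthetic.CohortConfig(
            datasets=[
                synthetic.DatasetSpec(f"SYN{d}", n_per_group, n_per_group)
                for d in range(n_datasets)
            ],
            plan=plan,
        )
        feats, subjects = synthetic.simulate_feature_table(cfg, seed + 5000 + s)
        res = pipeline.run_analyze(feats, subjects)
        for b in planted:
            v = res.verdicts.get(b)
            if v is not None and v.robust:
                hits[b] += 1
    return {b: h / n_seeds for b, h in hits.items()}
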