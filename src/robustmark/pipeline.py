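"""End-to-end orchestration: extract biomarkers, analyze groups, adjudicate.

``run_extract`` turns a cohort manifest (audio + transcript paths per
subject x task) into a long-format biomarker table with per-row flags;
``run_analyze`` computes the per-dataset group statistics, severity
correlations and robustness verdicts from that table.

Missingness policy: extraction failures are recorded per row and analysis
proceeds per biomarker on the subjects available, with group sizes recorded
per cell; a dataset x task cell with fewer than two subjects in either group
is skipped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acoustic, audio, cognitive, linguistic, stats
from .robustness import (
    ExpectedBehavior,
    RobustnessVerdict,
    adjudicate,
    load_expected_behavior,
    robust_set,
)

__all__ = [
    "ExtractConfig",
    "AnalysisResult",
    "BIOMARKER_FAMILY",
    "SEVERITY_SCALES",
    "extract_recording",
    "run_extract",
    "run_analyze",
]

log = logging.getLogger("robustmark")

ACOUSTIC_NAMES = (
    "F0STD", "F1STD", "INTSTD",
    "SPTIME", "SILTIME", "SILPERC", "SILSPRAT", "SILDUR", "SILVAR",
)

#: biomarker -> family used for FDR grouping
BIOMARKER_FAMILY: dict[str, str] = (
    {b: "acoustic" for b in ACOUSTIC_NAMES}
    | {b: "linguistic" for b in linguistic.LINGUISTIC_FEATURE_NAMES}
    | {"RHYSTD": "cognitive", "IU": "cognitive"}
)

#: manifest column -> reported scale name
SEVERITY_SCALES = {"updrs3": "UPDRS-III", "updrs3_1": "UPDRS-III.I", "hy": "H&Y"}


@dataclass
class ExtractConfig:
    """Parameters of the extraction stage, logged with every run."""

    target_rate: int = audio.TARGET_RATE
    loudness_target_db: float = -23.0
    pitch_floor: float = audio.PITCH_FLOOR
    pitch_ceiling: float = audio.PITCH_CEILING
    min_pause: float = audio.MIN_PAUSE
    min_speech: float = audio.MIN_SPEECH
    compute_f1: bool = True
    #: dataset name -> IUChecklist (informational units are computed only
    #: where a checklist is configured)
    checklists: dict = field(default_factory=dict)


def extract_recording(
    wav_path: str,
    transcript_path: str | None,
    task: str,
    config: ExtractConfig,
    checklist=None,
) -> list[tuple[str, float, str]]:
    """Extract all biomarkers of one recording.

    Returns ``(biomarker, value, flag)`` triples; a NaN value always carries
    a non-empty reason flag.
    """
    rows: list[tuple[str, float, str]] = []
    w = audio.read_wav(wav_path)
    if w.rate != config.target_rate:
        w = audio.resample(w, config.target_rate)

    seg = audio.detect_speech_pauses(w, config.min_pause, config.min_speech)
    try:
        pf = acoustic.pause_features(seg)
        n_pauses = len(seg.durations("pause"))
        flag = "" if n_pauses >= 2 else "few_pauses"
        for name in acoustic.PAUSE_FEATURE_NAMES:
            rows.append((name, pf[name], flag))
    except ValueError:
        for name in acoustic.PAUSE_FEATURE_NAMES:
            rows.append((name, float("nan"), "no_speech"))

    f0 = audio.f0_contour(w, config.pitch_floor, config.pitch_ceiling)
    v = acoustic.contour_std(f0)
    rows.append(("F0STD", v, "" if np.isfinite(v) else "lt2_voiced_frames"))

    norm = audio.normalize_loudness(w, config.loudness_target_db)
    iv = acoustic.contour_std(audio.intensity_contour(norm))
    rows.append(("INTSTD", iv, "" if np.isfinite(iv) else "lt2_active_frames"))

    if config.compute_f1:
        fv = acoustic.contour_std(audio.f1_contour(w, f0))
        rows.append(("F1STD", fv, "" if np.isfinite(fv) else "lt2_voiced_frames"))
    else:
        rows.append(("F1STD", float("nan"), "f1_disabled"))

    # transcript-based features
    if transcript_path:
        t = linguistic.read_conllu(transcript_path)
        if task == "SS":
            for name, value in (
                linguistic.lexical_counts(t) | linguistic.pos_counts(t)
            ).items():
                rows.append(
                    (name, value, "" if np.isfinite(value) else "no_content_words")
                )
            try:
                for name, value in linguistic.phrase_counts(t).items():
                    rows.append((name, value, ""))
            except linguistic.MissingLayerError:
                for name in ("NPCNT", "VPCNT", "PPCNT"):
                    rows.append((name, float("nan"), "no_phrase_layer"))
            if checklist is not None:
                rows.append(
                    ("IU", float(cognitive.informational_units(t.lemmas, checklist)), "")
                )
        onsets = t.word_onsets()
        if onsets:
            r = cognitive.rhythm_std_fluent(onsets, segmentation=seg)
            rows.append(("RHYSTD", r, "" if np.isfinite(r) else "lt2_fluent_intervals"))
        else:
            rows.append(("RHYSTD", float("nan"), "no_alignment"))
    else:
        if task == "SS":
            for name in linguistic.LINGUISTIC_FEATURE_NAMES:
                rows.append((name, float("nan"), "no_transcript"))
        rows.append(("RHYSTD", float("nan"), "no_transcript"))
    return rows


def run_extract(manifest: pd.DataFrame, config: ExtractConfig | None = None) -> pd.DataFrame:
    """Extract the biomarker table for every manifest row.

    Row-level failures are recorded (biomarker ``ERROR`` with the message in
    the flag) and the run continues; if every row fails, raises.
    """
    config = config or ExtractConfig()
    log.info("extraction parameters: %s", config)
    out = []
    n_failed = 0
    for rec in manifest.itertuples():
        transcript = getattr(rec, "transcript_path", "") or None
        if isinstance(transcript, float):  # NaN from CSV round-trip
            transcript = None
        checklist = config.checklists.get(rec.dataset)
        try:
            rows = extract_recording(
                rec.audio_path, transcript, rec.task, config, checklist
            )
        except Exception as exc:  # noqa: BLE001 - row-level fault isolation
            log.warning("extraction failed for %s/%s: %s", rec.subject_id, rec.task, exc)
            n_failed += 1
            out.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "dataset": rec.dataset,
                    "task": rec.task,
                    "biomarker": "ERROR",
                    "value": float("nan"),
                    "flag": str(exc),
                }
            )
            continue
        for name, value, flag in rows:
            out.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "dataset": rec.dataset,
                    "task": rec.task,
                    "biomarker": name,
                    "value": value,
                    "flag": flag,
                }
            )
    if len(manifest) and n_failed == len(manifest):
        raise RuntimeError("extraction failed for every manifest row")
    return pd.DataFrame(out)


@dataclass
class AnalysisResult:
    tests: pd.DataFrame
    correlations: pd.DataFrame
    verdicts: dict[str, RobustnessVerdict]

    @property
    def robust(self) -> list[str]:
        return robust_set(self.verdicts)


def _bh_within_families(df: pd.DataFrame, alpha: float) -> pd.DataFrame:
    df = df.copy()
    df["p_adj"] = np.nan
    df["significant"] = False
    for _, idx in df.groupby(["dataset", "task", "family"]).groups.items():
        p_adj, reject = stats.bh_adjust(df.loc[idx, "p"].to_numpy(), alpha)
        df.loc[idx, "p_adj"] = p_adj
        df.loc[idx, "significant"] = reject
    return df


def run_analyze(
    features: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
    alpha: float = stats.ALPHA,
    expected: ExpectedBehavior | None = None,
    min_group: int = 2,
) -> AnalysisResult:
    """Group statistics, severity correlations and robustness verdicts.

    ``features`` is the long table from :func:`run_extract` (or the
    audio-free simulator); ``subjects`` supplies severity scores per subject
    for the correlation stage (PD subjects only carry scores).  Analysis is
    performed within each dataset separately.
    """
    expected = expected or load_expected_behavior()
    feats = features[features["biomarker"].isin(BIOMARKER_FAMILY)].copy()
    feats = feats[np.isfinite(feats["value"])]

    test_rows = []
    for (dataset, task, biomarker), sub in feats.groupby(
        ["dataset", "task", "biomarker"]
    ):
        cn = sub.loc[sub["group"] == "CN", "value"].to_numpy()
        pd_ = sub.loc[sub["group"] == "PD", "value"].to_numpy()
        if len(cn) < min_group or len(pd_) < min_group:
            warnings.warn(
                f"skipping {dataset}/{task}/{biomarker}: a group has fewer "
                f"than {min_group} subjects",
                stacklevel=2,
            )
            continue
        h, p = stats.kruskal_wallis(cn, pd_)
        test_rows.append(
            {
                "dataset": dataset,
                "task": task,
                "biomarker": biomarker,
                "family": BIOMARKER_FAMILY[biomarker],
                "n_cn": len(cn),
                "n_pd": len(pd_),
                "H": h,
                "p": p,
                "OB": stats.observed_behavior(cn, pd_),
                "eta2": stats.eta_squared_from_h(h, len(cn) + len(pd_), 2),
                "auroc": stats.auroc(cn, pd_),
            }
        )
    tests = pd.DataFrame(test_rows)
    if len(tests):
        tests = _bh_within_families(tests, alpha)

    corr_rows = []
    if subjects is not None:
        scores = subjects.set_index("subject_id")
        pd_feats = feats[feats["group"] == "PD"]
        for (dataset, task, biomarker), sub in pd_feats.groupby(
            ["dataset", "task", "biomarker"]
        ):
            merged = sub.join(scores[list(SEVERITY_SCALES)], on="subject_id")
            # standardization before correlation (rank-invariant, applied as
            # a matter of procedure)
            v = merged["value"].to_numpy(dtype=float)
            if len(v) < 3 or np.nanstd(v) == 0:
                continue
            z = (v - np.nanmean(v)) / np.nanstd(v)
            for col, scale in SEVERITY_SCALES.items():
                s = pd.to_numeric(merged[col], errors="coerce").to_numpy(dtype=float)
                ok = np.isfinite(z) & np.isfinite(s)
                if ok.sum() < 3:
                    continue
                rho, p = stats.spearman(z[ok], s[ok])
                if not np.isfinite(rho):
                    continue
                corr_rows.append(
                    {
                        "dataset": dataset,
                        "task": task,
                        "biomarker": biomarker,
                        "family": BIOMARKER_FAMILY[biomarker],
                        "scale": scale,
                        "n": int(ok.sum()),
                        "rho": rho,
                        "p": p,
                    }
                )
    correlations = pd.DataFrame(corr_rows)
    if len(correlations):
        correlations = _bh_within_families(correlations, alpha)

    verdicts = adjudicate(expected, tests, correlations if len(correlations) else None,
                          alpha) if len(tests) else {}
    return AnalysisResult(tests, correlations, verdicts)
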