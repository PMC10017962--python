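"""Synthetic two-group speech cohorts with plantable effects.

The six clinical datasets the analysis was designed for are access-restricted,
so this module generates stand-in cohorts in which every biomarker the
pipeline measures has a controllable generative ground truth: per-subject
parameters (pitch mean/SD, intensity SD, pause rate and lognormal pause
durations, word rate and rhythm jitter, narrative length, POS composition,
checklist coverage) drive both a symbolic recording plan (word onsets,
speech/pause segmentation, F0/intensity/F1 tracks, annotated transcript) and,
optionally, rendered 16 kHz audio (harmonic pulse train through a single
time-varying resonance).

An :class:`EffectPlan` plants group differences as Cohen's-d shifts on the
generative parameters, per task class, and links parameters to clinical
severity scores through a shared latent severity factor (Gaussian copula, so
a target Spearman correlation is hit in expectation).

Two consumption routes exist:

* :func:`generate_cohort` writes WAV + CoNLL-U + manifest + ground truth to
  disk — the full pipeline's input contract;
* :func:`simulate_feature_table` computes biomarker values directly from the
  symbolic plan using the same downstream feature functions, skipping only
  waveform rendering — cheap enough for replicate calibration studies.

All randomness flows from one integer seed through per-subject counter-keyed
streams, so any single subject is reproducible without regenerating the
cohort.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from .acoustic import pause_features
from .audio import Segmentation, Waveform
from .cognitive import IUChecklist, informational_units, rhythm_std_fluent
from .linguistic import (
    FUNCTION_WORD_UPOS,
    AnnotatedTranscript,
    Token,
    lexical_counts,
    phrase_counts,
    pos_counts,
)

__all__ = [
    "EffectPlan",
    "SubjectParams",
    "DatasetSpec",
    "CohortConfig",
    "CohortBundle",
    "CohortModel",
    "SymbolicRecording",
    "plant_effects",
    "table4_effect_plan",
    "plan_symbolic",
    "render_audio",
    "synthesize_recording",
    "symbolic_features",
    "simulate_feature_table",
    "generate_cohort",
    "dataset_checklist",
    "PARAM_SPECS",
    "biomarker_parameter",
]

TASK_CLASSES = ("SS", "RP", "TDU")

#: Default recording-duration targets per task (s).  The spontaneous task is
#: long enough that planted narrative-length differences are never truncated.
DEFAULT_DURATIONS = {"SS": 120.0, "RP": 60.0, "TDU": 45.0}

#: Scripted token counts for the reading-like tasks (narrative length is a
#: subject trait only in spontaneous speech).
SCRIPT_LENGTH = {"RP": 80, "TDU": 50}

#: Token classes emitted by the lexicon.  AUX is a closed (function) class
#: but has its own biomarker, so it gets its own weight.
POS_WEIGHT_CLASSES = ("NOUN", "VERB", "ADJ", "ADV", "NUM", "AUX", "DET", "PRON", "ADP")

#: Generative parameter specs: (population mean, between-subject SD, lo, hi).
#: POS composition parameters (``w_<CLASS>``) live on the log-weight scale.
#: Weights are chosen so every counted class occurs often enough per
#: narrative that its count measures composition rather than Poisson noise.
PARAM_SPECS: dict[str, tuple[float, float, float, float]] = {
    "f0_mean": (150.0, 20.0, 75.0, 320.0),
    "f0_sd": (22.0, 6.0, 1.0, 80.0),
    "intensity_sd": (4.0, 1.0, 0.3, 12.0),
    "f1_mean": (520.0, 40.0, 300.0, 800.0),
    "f1_sd": (60.0, 15.0, 3.0, 200.0),
    "pause_rate": (0.35, 0.08, 0.02, 0.90),
    "pause_log_mean": (math.log(0.5), 0.30, -2.3, 0.7),
    "pause_log_sd": (0.45, 0.10, 0.05, 1.0),
    "word_rate": (2.5, 0.30, 1.0, 5.0),
    "rhythm_jitter": (0.080, 0.025, 0.002, 0.35),
    "n_words": (160.0, 35.0, 20.0, 400.0),
    "words_per_sentence": (9.0, 0.8, 3.0, 20.0),
    "word_len_mean": (6.0, 0.6, 3.0, 10.0),
    "iu_coverage": (0.65, 0.12, 0.02, 1.0),
    "w_NOUN": (math.log(0.21), 0.35, None, None),
    "w_VERB": (math.log(0.15), 0.35, None, None),
    "w_ADJ": (math.log(0.08), 0.35, None, None),
    "w_ADV": (math.log(0.08), 0.35, None, None),
    "w_NUM": (math.log(0.04), 0.35, None, None),
    "w_AUX": (math.log(0.07), 0.35, None, None),
    "w_DET": (math.log(0.13), 0.20, None, None),
    "w_PRON": (math.log(0.10), 0.20, None, None),
    "w_ADP": (math.log(0.14), 0.20, None, None),
}


def biomarker_parameter(biomarker: str, task_class: str) -> tuple[str, int]:
    """Generative parameter (name, sign) behind a biomarker in a task class.

    The sign says whether the biomarker increases (+1) or decreases (-1)
    with the parameter.  Unknown biomarker names are rejected.
    """
    fixed = {
        "F0STD": ("f0_sd", +1),
        "F1STD": ("f1_sd", +1),
        "INTSTD": ("intensity_sd", +1),
        "SILTIME": ("pause_rate", +1),
        "SILPERC": ("pause_rate", +1),
        "SILSPRAT": ("pause_rate", +1),
        "SILDUR": ("pause_log_mean", +1),
        "SILVAR": ("pause_log_sd", +1),
        "WORDCNT": ("n_words", +1),
        "WORDLEN": ("word_len_mean", +1),
        "SENTCNT": ("n_words", +1),
        "SENTLEN": ("words_per_sentence", +1),
        "NOUNCNT": ("w_NOUN", +1),
        "VERBCNT": ("w_VERB", +1),
        "ADJCNT": ("w_ADJ", +1),
        "ADVCNT": ("w_ADV", +1),
        "NUMCNT": ("w_NUM", +1),
        "AUXCNT": ("w_AUX", +1),
        "NPCNT": ("w_NOUN", +1),
        "VPCNT": ("w_VERB", +1),
        "PPCNT": ("w_ADP", +1),
        "IU": ("iu_coverage", +1),
        "RHYSTD": ("rhythm_jitter", +1),
    }
    if biomarker == "SPTIME":
        # spontaneous narratives get longer with more words; scripted tasks
        # get longer when read more slowly
        return ("n_words", +1) if task_class == "SS" else ("word_rate", -1)
    if biomarker not in fixed:
        raise ValueError(f"unknown biomarker name: {biomarker!r}")
    return fixed[biomarker]


@dataclass(frozen=True)
class EffectPlan:
    """One planted group effect.

    ``magnitude`` is a Cohen's d on the underlying generative parameter
    (shift of the PD mean in between-subject SD units); ``severity_link`` is
    the target Spearman correlation between the PD parameter and clinical
    severity.
    """

    biomarker: str
    task_class: str
    direction: str | None  # "up" | "down" | None
    magnitude: float
    severity_link: float = 0.0

    def __post_init__(self) -> None:
        if self.task_class not in TASK_CLASSES:
            raise ValueError(f"unknown task class {self.task_class!r}")
        if self.direction not in ("up", "down", None):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.direction is None and self.magnitude != 0:
            raise ValueError("null direction requires zero magnitude")
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")
        if abs(self.severity_link) > 1:
            raise ValueError("severity_link must lie in [-1, 1]")
        biomarker_parameter(self.biomarker, self.task_class)  # validates name


@dataclass
class SubjectParams:
    """Realized generative parameters of one subject in one task class."""

    subject_id: str
    group: str  # "CN" | "PD"
    f0_mean: float
    f0_sd: float
    intensity_sd: float
    f1_mean: float
    f1_sd: float
    pause_rate: float
    pause_log_mean: float
    pause_log_sd: float
    word_rate: float
    rhythm_jitter: float
    n_words: int
    words_per_sentence: float
    word_len_mean: float
    pos_logw: dict[str, float]
    iu_coverage: float
    updrs3: float | None = None
    updrs3_1: float | None = None
    hy: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("CN", "PD"):
            raise ValueError("group must be CN or PD")
        if not (60.0 <= self.f0_mean <= 400.0):
            raise ValueError("f0_mean outside [60, 400] Hz")
        for name in ("pause_rate", "word_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.iu_coverage <= 1.0):
            raise ValueError("iu_coverage outside [0, 1]")
        if self.hy is not None and not (1 <= self.hy <= 5):
            raise ValueError("H&Y stage outside [1, 5]")

    @property
    def mean_pause(self) -> float:
        return math.exp(self.pause_log_mean + self.pause_log_sd**2 / 2)

    def pos_weights(self) -> dict[str, float]:
        w = {c: math.exp(self.pos_logw[c]) for c in POS_WEIGHT_CLASSES}
        total = sum(w.values())
        return {c: v / total for c, v in w.items()}


# ---------------------------------------------------------------------------
# Effect planting


class CohortModel:
    """Group-level parameter distributions implied by an effect plan.

    PD means are shifted from the CN (base) means by ``direction x magnitude``
    between-subject SDs of the generative parameter; parameters with a
    severity link share a latent severity factor with the clinical scores.
    When several planted biomarkers map to one parameter the largest
    magnitude wins; conflicting directions on one parameter are an error.
    """

    def __init__(self, plan: list[EffectPlan], base: dict | None = None):
        self.specs = dict(PARAM_SPECS)
        if base:
            for k, v in base.items():
                if k not in self.specs:
                    raise ValueError(f"unknown generative parameter {k!r}")
                mean, sd, lo, hi = self.specs[k]
                self.specs[k] = (float(v), sd, lo, hi)
        # (param, task_class) -> signed shift in SD units
        self.shifts: dict[tuple[str, str], float] = {}
        # param -> Pearson latent loading (from the target Spearman)
        self.links: dict[str, float] = {}
        for entry in plan:
            if entry.direction is None or entry.magnitude == 0:
                continue
            param, sign = biomarker_parameter(entry.biomarker, entry.task_class)
            shift = entry.magnitude * (1 if entry.direction == "up" else -1) * sign
            key = (param, entry.task_class)
            if key in self.shifts and self.shifts[key] * shift < 0:
                raise ValueError(
                    f"conflicting planted directions on parameter {param!r} "
                    f"in task class {entry.task_class}"
                )
            if key not in self.shifts or abs(shift) > abs(self.shifts[key]):
                self.shifts[key] = shift
            if entry.severity_link:
                rho_s = entry.severity_link * sign
                lam = 2.0 * math.sin(math.pi * rho_s / 6.0)
                if param not in self.links or abs(lam) > abs(self.links[param]):
                    self.links[param] = lam

    def is_null(self) -> bool:
        return not self.shifts

    def draw_subject(
        self, subject_id: str, group: str, rng: np.random.Generator
    ) -> dict[str, "SubjectParams"]:
        """Draw one subject: params per task class sharing subject latents."""
        z_sev = rng.standard_normal()
        z: dict[str, float] = {}
        for param in self.specs:
            eps = rng.standard_normal()
            lam = self.links.get(param, 0.0) if group == "PD" else 0.0
            z[param] = lam * z_sev + math.sqrt(max(0.0, 1 - lam**2)) * eps
        severity = self._severity(z_sev, rng) if group == "PD" else {}
        out = {}
        for task in TASK_CLASSES:
            values = {}
            for param, (mean, sd, lo, hi) in self.specs.items():
                shift = self.shifts.get((param, task), 0.0) if group == "PD" else 0.0
                v = mean + sd * (z[param] + shift)
                if lo is not None:
                    v = min(max(v, lo), hi)
                values[param] = v
            # physical cap: time spent pausing cannot approach real time
            mean_pause = math.exp(
                values["pause_log_mean"] + values["pause_log_sd"] ** 2 / 2
            )
            values["pause_rate"] = min(
                values["pause_rate"], 0.85 / mean_pause
            )
            out[task] = SubjectParams(
                subject_id=subject_id,
                group=group,
                f0_mean=values["f0_mean"],
                f0_sd=values["f0_sd"],
                intensity_sd=values["intensity_sd"],
                f1_mean=values["f1_mean"],
                f1_sd=values["f1_sd"],
                pause_rate=values["pause_rate"],
                pause_log_mean=values["pause_log_mean"],
                pause_log_sd=values["pause_log_sd"],
                word_rate=values["word_rate"],
                rhythm_jitter=values["rhythm_jitter"],
                n_words=int(round(values["n_words"])),
                words_per_sentence=values["words_per_sentence"],
                word_len_mean=values["word_len_mean"],
                pos_logw={c: values[f"w_{c}"] for c in POS_WEIGHT_CLASSES},
                iu_coverage=values["iu_coverage"],
                **severity,
            )
        return out

    @staticmethod
    def _severity(z_sev: float, rng: np.random.Generator) -> dict:
        """Clinical scores driven by the latent severity factor.

        UPDRS-III is kept continuous so its ranks are informative; the
        speech item and H&Y are coarser, as in clinical practice.
        """
        z2 = 0.9 * z_sev + math.sqrt(1 - 0.81) * rng.standard_normal()
        updrs3 = float(np.clip(25.0 + 9.0 * z_sev, 3.0, 80.0))
        updrs3_1 = float(np.clip(1.6 + 0.7 * z2, 0.0, 4.0))
        hy = int(np.digitize(z_sev, [-0.5, 0.8]) + 1)
        return {"updrs3": updrs3, "updrs3_1": updrs3_1, "hy": hy}


def plant_effects(plan: list[EffectPlan], base: dict | None = None) -> CohortModel:
    """Build group-level parameter distributions from an effect plan."""
    return CohortModel(plan, base)


def table4_effect_plan(
    magnitude: float = 1.5, severity_link: float = 0.5
) -> list[EffectPlan]:
    """An effect plan replicating the expected PD behavior of every
    biomarker: the spontaneous-task direction for all, the reading direction
    for speech time and rhythm in the scripted tasks, and severity links
    signed to match each direction."""
    from .robustness import load_expected_behavior

    expected = load_expected_behavior()
    plan = []
    for (biomarker, task_class), direction in expected.directions.items():
        classes = TASK_CLASSES if task_class == "All" else (task_class,)
        for tc in classes:
            link = severity_link if direction == "up" else -severity_link
            plan.append(EffectPlan(biomarker, tc, direction, magnitude, link))
    return plan


# ---------------------------------------------------------------------------
# Lexicon


_CONSONANTS = "bdfgklmnprstv"
_VOWELS = "aeiou"

_FUNCTION_FORMS = {
    "DET": ("da", "de", "du"),
    "PRON": ("pa", "pe", "pi", "po"),
    "ADP": ("ka", "ke", "ko"),
    "AUX": ("es", "et", "en"),
}


def _pseudo_word(length: int, rng: np.random.Generator) -> str:
    chars = []
    for i in range(max(2, length)):
        pool = _CONSONANTS if i % 2 == 0 else _VOWELS
        chars.append(pool[rng.integers(len(pool))])
    return "".join(chars)


def dataset_checklist(dataset: str, n_items: int = 13) -> IUChecklist:
    """Deterministic per-dataset informational-unit checklist.

    Each synthetic language gets its own checklist of salient picture
    events, mirroring how published checklists are language-specific.
    """
    items = [frozenset({f"iu_{dataset.lower()}_{i}"}) for i in range(n_items)]
    return IUChecklist(task="picture_description", language=dataset, items=items)


# ---------------------------------------------------------------------------
# Symbolic synthesis


@dataclass
class SymbolicRecording:
    """Everything about a recording except the waveform itself."""

    transcript: AnnotatedTranscript
    segmentation: Segmentation
    word_times: list[tuple[float, float]]
    f0_grid_step: float
    f0_track: np.ndarray  # per 10 ms grid point over the whole recording
    word_level_db: np.ndarray  # per word
    word_f1_hz: np.ndarray  # per word
    duration: float
    params: SubjectParams
    task: str


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) series."""
    eps = rng.standard_normal(n)
    x = scipy.signal.lfilter([1.0], [1.0, -phi], eps * math.sqrt(1 - phi**2))
    x[0] = eps[0]
    return x


def plan_symbolic(
    params: SubjectParams,
    task: str,
    duration_target: float,
    rng: np.random.Generator,
    checklist: IUChecklist | None = None,
) -> SymbolicRecording:
    """Plan a recording: tokens, timing, segmentation, and control tracks.

    The audio, if rendered, follows this plan exactly, so the plan doubles
    as ground truth for every extractor.
    """
    if duration_target <= 1.0:
        raise ValueError("duration target must exceed 1 s")
    if params.pause_rate * params.mean_pause >= 1.0:
        raise ValueError(
            "infeasible pause configuration: pause_rate x mean pause >= 1 s/s"
        )
    # recordings start and end on speech: edge silences are trimmed in
    # pre-processing anyway, and leaving them in would dilute the pause
    # statistics with artifacts of the synthesis
    edge = 0.0
    n_tokens = params.n_words if task == "SS" else SCRIPT_LENGTH[task]
    n_tokens = max(int(n_tokens), 5)
    weights = params.pos_weights()
    classes = list(weights)
    probs = np.array([weights[c] for c in classes])

    # token sequence
    upos_seq = [classes[i] for i in rng.choice(len(classes), size=n_tokens, p=probs)]
    iu_lemmas: list[str] = []
    if task == "SS" and checklist is not None:
        covered = [
            sorted(item)[0]
            for item in checklist.items
            if rng.random() < params.iu_coverage
        ]
        slots = rng.choice(n_tokens, size=min(len(covered), n_tokens), replace=False)
        iu_at = dict(zip(slots.tolist(), covered))
    else:
        iu_at = {}

    tokens: list[Token] = []
    sent_index = 0
    sent_len = 0
    sent_target = max(3, int(round(rng.normal(params.words_per_sentence, 2.0))))
    word_times: list[tuple[float, float]] = []
    seg_bounds: list[tuple[float, float]] = []  # speech runs
    t = edge
    run_start = t
    p_pause = min(0.9, params.pause_rate / params.word_rate)
    for i, upos in enumerate(upos_seq):
        if i in iu_at:
            upos = "VERB"
            form = lemma = iu_at[i]
        elif upos in _FUNCTION_FORMS:
            form = lemma = _FUNCTION_FORMS[upos][rng.integers(len(_FUNCTION_FORMS[upos]))]
        else:
            length = int(round(rng.normal(params.word_len_mean, 1.2)))
            form = lemma = _pseudo_word(min(max(length, 3), 12), rng)
        dur = max(0.06, 1.0 / params.word_rate + rng.normal(0.0, params.rhythm_jitter))
        start, end = t, t + dur
        if end > duration_target:
            break
        word_times.append((start, end))
        tokens.append(
            Token(form, lemma, upos, upos in FUNCTION_WORD_UPOS, sent_index, start, end)
        )
        t = end
        sent_len += 1
        if sent_len >= sent_target:
            sent_index += 1
            sent_len = 0
            sent_target = max(3, int(round(rng.normal(params.words_per_sentence, 2.0))))
        if i < n_tokens - 1 and rng.random() < p_pause:
            pause = float(
                np.clip(
                    rng.lognormal(params.pause_log_mean, params.pause_log_sd),
                    0.18,
                    5.0,
                )
            )
            seg_bounds.append((run_start, t))
            t += pause
            run_start = t
    if not word_times:
        raise ValueError("no words fit within the duration target")
    if t > run_start + 1e-9:
        seg_bounds.append((run_start, t))
    duration = t + edge

    intervals: list[tuple[float, float, str]] = []
    if seg_bounds[0][0] > 0:
        intervals.append((0.0, seg_bounds[0][0], "pause"))
    for j, (s, e) in enumerate(seg_bounds):
        intervals.append((s, e, "speech"))
        nxt = seg_bounds[j + 1][0] if j + 1 < len(seg_bounds) else duration
        if nxt > e:
            intervals.append((e, nxt, "pause"))
    segmentation = Segmentation(intervals, duration)

    # phrase spans from POS structure: every noun heads an NP (with an
    # adjacent determiner), every verb a VP (with an adjacent auxiliary),
    # every adposition followed closely by a noun a PP
    spans: list[tuple[str, int, int]] = []
    for i, tok in enumerate(tokens):
        if tok.upos == "NOUN":
            a = i - 1 if i > 0 and tokens[i - 1].upos == "DET" else i
            spans.append(("NP", a, i))
        elif tok.upos == "VERB":
            a = i - 1 if i > 0 and tokens[i - 1].upos == "AUX" else i
            spans.append(("VP", a, i))
        elif tok.upos == "ADP":
            for j in range(i + 1, min(i + 4, len(tokens))):
                if tokens[j].upos == "NOUN":
                    spans.append(("PP", i, j))
                    break
    transcript = AnnotatedTranscript(tokens, sorted(spans, key=lambda s: s[1]))

    grid = 0.010
    n_grid = int(math.ceil(duration / grid)) + 1
    f0_track = params.f0_mean + params.f0_sd * _ar1(n_grid, 0.95, rng)
    f0_track = np.clip(f0_track, 60.0, 400.0)
    n_words = len(word_times)
    level = -26.0 + params.intensity_sd * _ar1(n_words, 0.7, rng)
    f1 = np.clip(
        params.f1_mean + params.f1_sd * _ar1(n_words, 0.8, rng), 250.0, 1100.0
    )
    return SymbolicRecording(
        transcript=transcript,
        segmentation=segmentation,
        word_times=word_times,
        f0_grid_step=grid,
        f0_track=f0_track,
        word_level_db=level,
        word_f1_hz=f1,
        duration=duration,
        params=params,
        task=task,
    )


# ---------------------------------------------------------------------------
# Audio rendering


def render_audio(sym: SymbolicRecording, rate: int = 16_000) -> Waveform:
    """Render the symbolic plan as a waveform.

    Voiced source: sum of the first 8 harmonics of the planned F0 track with
    1/k amplitude roll-off, shaped by one second-order resonance per word
    (the first formant) and rescaled to the word's planned RMS level.
    Silences are exact zeros.
    """
    n_total = int(math.ceil(sym.duration * rate))
    y = np.zeros(n_total)
    grid_t = np.arange(len(sym.f0_track)) * sym.f0_grid_step
    ramp_n = int(0.010 * rate)
    for w, (start, end) in enumerate(sym.word_times):
        i0, i1 = int(start * rate), int(end * rate)
        n = i1 - i0
        if n <= 2 * ramp_n or n <= 0:
            continue
        tt = np.arange(n) / rate + start
        f0 = np.interp(tt, grid_t, sym.f0_track)
        phase = 2 * np.pi * np.cumsum(f0) / rate
        x = np.zeros(n)
        for k in range(1, 9):
            x += np.sin(k * phase) / k
        # single-resonance vocal tract, constant within the word
        f1 = sym.word_f1_hz[w]
        bw = 120.0
        r = math.exp(-math.pi * bw / rate)
        theta = 2 * math.pi * f1 / rate
        b = [1 - r]
        a = [1.0, -2 * r * math.cos(theta), r * r]
        x = scipy.signal.lfilter(b, a, x)
        ramp = np.ones(n)
        ramp[:ramp_n] = np.linspace(0.0, 1.0, ramp_n)
        ramp[-ramp_n:] = np.linspace(1.0, 0.0, ramp_n)
        x *= ramp
        rms = math.sqrt(float(np.mean(x**2)))
        if rms > 0:
            x *= 10 ** (sym.word_level_db[w] / 20.0) / rms
        y[i0:i1] += x
    peak = np.abs(y).max()
    if peak > 0.99:  # headroom guard; uniform, so contour SDs are unaffected
        y *= 0.99 / peak
    return Waveform(y, rate)


def synthesize_recording(
    params: SubjectParams,
    task: str,
    duration_target: float,
    rng: np.random.Generator,
    checklist: IUChecklist | None = None,
) -> tuple[Waveform, AnnotatedTranscript]:
    """Plan and render one recording; returns audio plus the time-anchored
    annotated transcript."""
    sym = plan_symbolic(params, task, duration_target, rng, checklist)
    return render_audio(sym), sym.transcript


# ---------------------------------------------------------------------------
# Feature ground truth (audio-free route)


def symbolic_features(
    sym: SymbolicRecording, checklist: IUChecklist | None = None
) -> dict[str, float]:
    """Biomarker values computed from the symbolic plan.

    Uses the same downstream feature functions as the audio pipeline
    (pause statistics from the segmentation, rhythm from word onsets,
    lexical/POS/phrase counts from the transcript) and reads the contour
    SDs from the planned control tracks, skipping only waveform rendering
    and contour re-estimation.
    """
    out: dict[str, float] = {}
    out.update(pause_features(sym.segmentation))
    # contour variability over speech time
    grid_t = np.arange(len(sym.f0_track)) * sym.f0_grid_step
    in_speech = np.zeros(len(grid_t), dtype=bool)
    for s, e, lab in sym.segmentation.intervals:
        if lab == "speech":
            in_speech |= (grid_t >= s) & (grid_t < e)
    out["F0STD"] = float(np.std(sym.f0_track[in_speech], ddof=1))
    # intensity/F1 contours are constant within a word: weight by duration
    durs = np.array([e - s for s, e in sym.word_times])
    reps = np.maximum(1, np.round(durs / 0.010).astype(int))
    out["INTSTD"] = float(np.std(np.repeat(sym.word_level_db, reps), ddof=1))
    out["F1STD"] = float(np.std(np.repeat(sym.word_f1_hz, reps), ddof=1))
    if sym.task == "SS":
        out.update(lexical_counts(sym.transcript))
        out.update(pos_counts(sym.transcript))
        out.update(phrase_counts(sym.transcript))
        if checklist is not None:
            out["IU"] = float(
                informational_units(sym.transcript.lemmas, checklist)
            )
    onsets = [s for s, _ in sym.word_times]
    out["RHYSTD"] = rhythm_std_fluent(onsets, segmentation=sym.segmentation)
    return out


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class DatasetSpec:
    name: str
    n_cn: int
    n_pd: int
    tasks: tuple[str, ...] = TASK_CLASSES
    has_transcripts: bool = True

    def __post_init__(self) -> None:
        if self.n_cn <= 0 or self.n_pd <= 0:
            raise ValueError(f"dataset {self.name!r} has an empty group")
        for t in self.tasks:
            if t not in TASK_CLASSES:
                raise ValueError(f"unknown task {t!r}")


@dataclass
class CohortConfig:
    datasets: list[DatasetSpec]
    plan: list[EffectPlan] = field(default_factory=list)
    base: dict = field(default_factory=dict)
    durations: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    iu_items: int = 13


@dataclass
class CohortBundle:
    manifest: pd.DataFrame
    ground_truth: dict[str, dict]
    out_dir: str | None = None


def _subject_rng(seed: int, d_idx: int, s_idx: int) -> np.random.Generator:
    """Counter-keyed per-subject stream: reproducible in isolation."""
    return np.random.default_rng([seed, d_idx, s_idx])


def _iter_subjects(config: CohortConfig):
    for d_idx, ds in enumerate(config.datasets):
        for s_idx in range(ds.n_cn + ds.n_pd):
            group = "CN" if s_idx < ds.n_cn else "PD"
            sid = f"{ds.name}_{group}{s_idx:03d}"
            yield d_idx, ds, s_idx, sid, group


def _check_config(config: CohortConfig) -> None:
    seen = set()
    for _, _, _, sid, _ in _iter_subjects(config):
        if sid in seen:
            raise ValueError(f"duplicate subject id {sid!r}")
        seen.add(sid)


def _params_record(by_task: dict[str, SubjectParams]) -> dict:
    rec = {}
    for task, p in by_task.items():
        rec[task] = {
            k: getattr(p, k)
            for k in (
                "f0_mean", "f0_sd", "intensity_sd", "f1_mean", "f1_sd",
                "pause_rate", "pause_log_mean", "pause_log_sd", "word_rate",
                "rhythm_jitter", "n_words", "words_per_sentence",
                "word_len_mean", "iu_coverage",
            )
        }
        rec[task]["pos_logw"] = dict(p.pos_logw)
    any_p = next(iter(by_task.values()))
    rec["severity"] = {
        "updrs3": any_p.updrs3,
        "updrs3_1": any_p.updrs3_1,
        "hy": any_p.hy,
    }
    return rec


def generate_cohort(
    config: CohortConfig, seed: int, out_dir: str
) -> CohortBundle:
    """Generate a multi-dataset cohort on disk.

    Writes per subject x task a 16 kHz mono WAV and a CoNLL-U transcript with
    word time anchors and chunk tags, plus ``manifest.csv``,
    ``ground_truth.json`` and a per-dataset IU checklist JSON.  Bit-identical
    output for identical (config, seed).
    """
    from .audio import write_wav
    from .linguistic import write_conllu

    _check_config(config)
    model = plant_effects(config.plan, config.base or None)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    truth: dict[str, dict] = {}
    for d_idx, ds, s_idx, sid, group in _iter_subjects(config):
        rng = _subject_rng(seed, d_idx, s_idx)
        by_task = model.draw_subject(sid, group, rng)
        truth[sid] = _params_record(by_task)
        checklist = dataset_checklist(ds.name, config.iu_items)
        ddir = os.path.join(out_dir, ds.name)
        os.makedirs(ddir, exist_ok=True)
        for task in ds.tasks:
            sym = plan_symbolic(
                by_task[task], task, config.durations[task], rng, checklist
            )
            wav_path = os.path.join(ddir, f"{sid}_{task}.wav")
            write_wav(wav_path, render_audio(sym))
            conllu_path = ""
            if ds.has_transcripts:
                conllu_path = os.path.join(ddir, f"{sid}_{task}.conllu")
                write_conllu(conllu_path, sym.transcript)
            p = by_task[task]
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "dataset": ds.name,
                    "task": task,
                    "audio_path": wav_path,
                    "transcript_path": conllu_path,
                    "updrs3": p.updrs3,
                    "updrs3_1": p.updrs3_1,
                    "hy": p.hy,
                }
            )
        with open(os.path.join(ddir, "iu_checklist.json"), "w") as fh:
            json.dump(
                {
                    "task": checklist.task,
                    "language": checklist.language,
                    "items": [sorted(i) for i in checklist.items],
                },
                fh,
                indent=1,
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    return CohortBundle(manifest, truth, out_dir)


def simulate_feature_table(
    config: CohortConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Audio-free cohort: biomarker table plus subject metadata.

    Returns ``(features, subjects)`` where ``features`` has columns
    subject_id/group/dataset/task/biomarker/value and ``subjects`` one row
    per subject with severity scores.  Used for replicate-heavy calibration
    studies where waveform rendering would dominate the cost.
    """
    _check_config(config)
    model = plant_effects(config.plan, config.base or None)
    feat_rows = []
    subj_rows = []
    for d_idx, ds, s_idx, sid, group in _iter_subjects(config):
        rng = _subject_rng(seed, d_idx, s_idx)
        by_task = model.draw_subject(sid, group, rng)
        checklist = dataset_checklist(ds.name, config.iu_items)
        p0 = by_task[ds.tasks[0]]
        subj_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "dataset": ds.name,
                "updrs3": p0.updrs3,
                "updrs3_1": p0.updrs3_1,
                "hy": p0.hy,
            }
        )
        for task in ds.tasks:
            sym = plan_symbolic(
                by_task[task], task, config.durations[task], rng, checklist
            )
            for biomarker, value in symbolic_features(sym, checklist).items():
                feat_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "dataset": ds.name,
                        "task": task,
                        "biomarker": biomarker,
                        "value": value,
                    }
                )
    return pd.DataFrame(feat_rows), pd.DataFrame(subj_rows)
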