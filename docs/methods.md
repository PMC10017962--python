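# Methods

This note documents the models, algorithmic choices and default parameters
behind `robustmark`, and what the synthetic validation does and does not
demonstrate.

## Biomarker definitions

**Acoustic.** F0STD, F1STD and INTSTD are sample standard deviations
(denominator n − 1, as everywhere an SD is named) of per-frame contours
computed on 40 ms windows with a 10 ms hop, over valid frames only: F0 and
F1 over voiced frames, intensity over frames within 50 dB of the loudest
frame. Restricting to valid frames keeps silence from inflating the
intensity SD and keeps F0 defined. The pause family comes from the
speech/pause segmentation: SPTIME and SILTIME are total speech and pause
time in seconds, SILPERC = 100·SILTIME/(SPTIME + SILTIME), SILSPRAT =
SILTIME/SPTIME, SILDUR is the mean pause duration and SILVAR the median
absolute deviation of pause durations. SPTIME is kept in seconds — the
ratio information is already carried by SILPERC/SILSPRAT, which are
strictly monotone transforms of each other and therefore identical under
every rank statistic downstream (a property the test suite asserts).
Recordings with no pauses yield defined zeros rather than missing values,
flagged, so cohorts stay rectangular.

**Linguistic.** Transcripts arrive annotated (CoNLL-U with Universal POS
tags, sentence boundaries, optional NP/VP/PP spans and word time anchors);
no tagging, parsing or alignment happens in this package — those are
adapter concerns, which also keeps the pipeline testable without
pretrained models. WORDCNT and WORDLEN are computed after function-word
removal; the function-word class defaults to the closed UPOS classes
{DET, PRON, ADP, CCONJ, SCONJ, PART, AUX, INTJ} and can be overridden per
language profile (an explicit `Func=` key on a token always wins). SENTLEN
is mean tokens per sentence over *all* tokens: function words carry
sentence-structural information, and removing them is specified only for
the word-level measures. POS and phrase counts are raw counts, not
per-word rates — narrative length differences are themselves part of the
phenomenon. A transcript without a phrase layer yields missing phrase
counts with a reason flag (mirroring languages for which no parser
exists).

**Cognitive.** RHYSTD is the sample SD of intervals between consecutive
word onsets. Two readings of this definition exist; this package computes
it over intervals *within fluent speech runs*, excluding intervals that
span a detected pause (`rhythm_std_fluent`; the plain `rhythm_std` is also
provided). Rationale: pause-spanning intervals make the measure a noisy
copy of the pause family — in any cohort where pausing increases, interval
SD increases mechanically, drowning the rhythm signal with the opposite
sign — whereas reduced pause-free interval SD and increased pausing are
observed simultaneously in real PD cohorts, which is only coherent for the
within-run measure (segment-wise forced alignment yields exactly this).
IU counts checklist items (each a set of acceptable lemmas, e.g.
{try, help} for a multi-word event) mentioned at least once — type
counting, so repetitions do not accumulate. English (13-item Cookie Theft)
and Spanish (4-item) checklists are packaged.

## Statistics

Group comparison uses the Kruskal–Wallis H-test with mid-rank tie
correction (scipy), with the convention that an all-tied cell returns
H = 0, p = 1 rather than an error. Effect size is the H-based
η² = (H − k + 1)/(n − k), floored at 0. AUROC is the tie-corrected rank
statistic A = [#(pd > cn) + ½#(ties)]/(n_cn·n_pd), reported as
max(A, 1 − A): direction is carried separately by the observed behavior
(sign of the PD − CN median difference), so reported AUROCs are ≥ 0.5 by
convention. FDR control is Benjamini–Hochberg (statsmodels) within each
biomarker family — {acoustic, linguistic, cognitive} × dataset × task —
at α = 0.05; the family granularity is configurable. Severity
correlations are Spearman coefficients on PD subjects (scores exist only
for PD), after per-biomarker standardization (a strictly monotone
transform, hence rank-neutral; asserted in tests), FDR-corrected the same
way.

p-values come from the chi-square approximation at every n, matching
standard practice; an exact-permutation mode (`kruskal_wallis_exact`)
exists for validation. The approximation's tail is accurate where
decisions are made — measured against exact enumeration at ≤ 8 per group,
|Δp| ≤ 0.02 for exact p ≤ 0.1 — but its mid-range error (p ≈ 0.2–0.5)
reaches ~0.05–0.12 at these sizes; that error is a property of the
approximation itself, so validation is scoped to the decision region.

## Robustness adjudication

Conditions are evaluated per task class against that class's expected
direction, and a biomarker name is robust if all three conditions hold in
at least one task class: (1) significant results in ≥ 2 distinct datasets,
(2) all significant results in the class show the expected direction,
(3) all significant severity correlations match the direction's sign
(vacuously true with none). Per-class evaluation matters because speech
time and rhythm have opposite expected directions in spontaneous versus
reading-like tasks; a reading-task reversal is a task-robustness issue,
not a language-robustness one. The expected-direction table, and encodings
of the published per-dataset test and correlation tables, ship as CSV
fixtures; three cells whose printed arrows contradict the surrounding
running text are encoded per the text, each carrying a provenance note in
the fixture.

## Synthetic cohorts

Real multi-language PD speech corpora are access-restricted, so validation
runs on generated cohorts in which every biomarker has a controllable
ground truth. Each subject draws generative parameters from population
distributions (mean, between-subject SD, clipped to plausible ranges):

| parameter | default (SD) | drives |
|---|---|---|
| f0_mean | 150 Hz (20) | pitch level |
| f0_sd | 22 Hz (6) | F0STD |
| intensity_sd | 4 dB (1) | INTSTD |
| f1_mean / f1_sd | 520 (40) / 60 (15) Hz | F1STD |
| pause_rate | 0.35 /s (0.08) | SILTIME, SILPERC, SILSPRAT |
| pause_log_mean / _sd | ln 0.5 (0.30) / 0.45 (0.10) | SILDUR / SILVAR |
| word_rate | 2.5 /s (0.30) | speech tempo; SPTIME in scripted tasks |
| rhythm_jitter | 80 ms (25) | RHYSTD |
| n_words | 160 (35) | narrative length: SPTIME (SS), WORDCNT, SENTCNT |
| words_per_sentence | 9 (0.8) | SENTLEN (and, inversely, SENTCNT) |
| word_len_mean | 6 chars (0.6) | WORDLEN |
| POS log-weights | see source (0.35 content / 0.20 function) | POS & phrase counts |
| iu_coverage | 0.65 (0.12) | IU |

Two couplings were deliberately calibrated at design time. First, POS
weights are set so every counted class occurs often enough per narrative
(numerals ≈ 4%, i.e. ~6 tokens) that its count measures composition rather
than Poisson noise. Second, the words-per-sentence spread is 0.8 — a
realistic speaker-level spread for a controlled elicitation task — because
planting shorter sentences pushes sentence *count* up for a fixed word
budget, and an exaggerated spread would make downward shifts in both
SENTLEN and SENTCNT jointly unrealizable. Pause rate is capped at
0.85/mean-pause so no subject pauses more than real time permits.

An effect plan plants group differences as Cohen's-d shifts of the PD mean
on a generative parameter, per task class (speech time maps to narrative
length in SS and inversely to word rate in scripted tasks). Severity
scores (UPDRS-III continuous, UPDRS-III.I, H&Y 1–3 ordinal) derive from a
latent severity factor; a parameter with severity link ρ_s loads on that
latent with Pearson λ = 2·sin(πρ_s/6), the Gaussian-copula inverse, so the
planted Spearman correlation is hit in expectation (verified by
Monte-Carlo to ±0.1).

Audio is rendered at 16 kHz as the sum of the first 8 harmonics of the
planned F0 track (1/k roll-off; F0 is a stationary AR(1), φ = 0.95 on the
10 ms grid, scaled to the subject SD), shaped by one second-order
resonance per word (the first formant, bandwidth 120 Hz) and rescaled to
the word's planned RMS level; silences are exact zeros; 10 ms cosine
ramps avoid clicks. Word durations are 1/word_rate + N(0, rhythm_jitter);
pauses are lognormal, inserted after a word with probability
pause_rate/word_rate and clipped to [0.18 s, 5 s] so every planted pause
is detectable. Transcripts use a synthetic lexicon (consonant–vowel
pseudo-words per POS class, closed function-word forms, lemma = form) —
POS structure, not vocabulary, is what the linguistic features consume.
Phrase spans follow fixed rules (every noun heads an NP, every verb a VP,
adposition + nearby noun a PP), so phrase counts track POS composition.

Besides full on-disk cohorts (WAV + CoNLL-U + manifest + ground truth;
bit-identical for identical config and seed, with counter-keyed
per-subject streams so any subject regenerates in isolation), a symbolic
route computes biomarkers directly from the recording plan using the same
downstream feature functions, skipping only waveform rendering — used for
replicate-heavy calibration where rendering would dominate cost.

## Validation studies and problem sizes

* **Parameter recovery** (audio route): 100 subjects, one 60 s spontaneous
  recording each, with pitch SD, intensity SD, mean pause duration and
  rhythm jitter swept independently over wide ranges and all other
  parameters at the prototype. Measured Spearman correlations between
  planted and extracted values exceed 0.9 for all four (threshold 0.8).
* **Null calibration** (symbolic route): 200 replicate cohorts of 20 + 20
  with no planted effects; the fraction of family instances with any BH
  rejection stays within α + 3 Monte-Carlo standard errors.
* **Plant-and-recover** (symbolic route): the full expected-behavior
  profile planted at d = 1.5 with ±0.5 severity links in 3 datasets of
  40 + 40; over 20 seeds, every one of the 24 planted biomarkers is
  adjudicated robust in ≥ 90% of seeds.

What this does and does not show: the generator produces clean harmonic
speech with exact-zero silences, error-free transcripts and anchors, and
no channel noise, reverberation, microphone variation or ASR errors.
Passing validation therefore demonstrates that the pipeline's measurement
and inference chain is correct and well calibrated — not that the
biomarkers themselves are robust in real clinical recordings, which is
exactly the question requiring the restricted corpora.

## Numerical and degenerate-input choices

* Pitch tracking: normalized autocorrelation, search 60–400 Hz, voicing
  when the peak ≥ 0.45 and frame energy within 35 dB of the maximum;
  parabolic lag interpolation; width-5 median filter over voiced estimates
  (octave-jump suppression). The same median smoothing stabilizes the
  LPC-based F1 track (order 10, pre-emphasis 0.97, lowest pole in
  200–1200 Hz with bandwidth < 500 Hz).
* VAD: 30 ms frames, 10 ms hop; threshold = noise floor (5th percentile
  of frame dB) + max(12 dB, 25% of the floor-to-speech (90th percentile)
  range); recordings with < 15 dB of dynamic range are treated as all
  speech (a continuous tone has no discernible silence). Pauses shorter
  than 0.15 s are merged into speech, then speech islands shorter than
  0.10 s into pause; intervals tile [0, duration] exactly. A simple
  percentile-only threshold was rejected: whenever true pauses occupy less
  than the percentile's share of frames it lands inside the speech level
  distribution and shreds quiet words into spurious pauses.
* Loudness normalization is a simplified integrated-loudness procedure
  (energy-weighted mean level over frames within 40 dB of the loudest,
  a relative gate, hence scale-invariant and idempotent) rather than the
  full broadcast gating/weighting standard; the intensity biomarker is the
  SD of a dB contour, invariant to the level shift, so only the uniform-
  level contract matters. Edge trimming for utterance concatenation reuses
  the VAD activity decision — one definition of silence throughout.
* Missing values always carry a reason flag (`no_transcript`,
  `no_phrase_layer`, `no_alignment`, `lt2_voiced_frames`, …); analysis
  proceeds per biomarker on available subjects with per-cell group sizes
  recorded, and a cell with fewer than 2 subjects in either group is
  skipped with a warning.

## Known limitations

* The generator's parameter ranges are chosen for plausibility; no public
  distributional data exists for the restricted cohorts, so absolute
  biomarker levels are not calibrated to any real population.
* IU counting is type-based and lemma-exact; paraphrases and fuzzy
  mentions are not matched.
* The adjudicator treats datasets as exchangeable evidence; there is no
  meta-analytic pooling or effect-size weighting.
* Jitter, shimmer, HNR and articulatory measures (VSA, FCR, VOT) are out
  of scope.
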