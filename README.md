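# robustmark

Cross-lingual robustness analysis of interpretable speech and language
biomarkers for Parkinson's disease (PD).

Hypokinetic dysarthria and the language changes of PD leave measurable
traces in recorded speech: reduced pitch and loudness variability
("monopitch", "monoloudness"), longer and more frequent pauses, shorter and
syntactically simpler narratives, less informative picture descriptions,
and a more static word-timing rhythm. A biomarker that shows these changes
in one language may be an artifact of one cohort's recording protocol; a
clinically useful biomarker should behave the same way across languages and
datasets. `robustmark` implements the full evaluation pipeline for this
question, aimed at speech-biomarker researchers:

* **extraction** of 24 interpretable biomarkers per recording — acoustic
  (F0STD, F1STD, INTSTD and the pause family SPTIME, SILTIME, SILPERC,
  SILSPRAT, SILDUR, SILVAR), linguistic (word/sentence counts and lengths,
  POS-class counts, NP/VP/PP phrase counts from annotated CoNLL-U
  transcripts), and cognitive (informational units against a checklist,
  word-onset rhythm variability RHYSTD);
* **group statistics** per dataset × task × biomarker: Kruskal–Wallis
  H-test (CN vs PD), Benjamini–Hochberg FDR correction within each
  biomarker family at α = 0.05, the H-based effect size
  η² = (H − k + 1)/(n − k), the tie-corrected AUROC reported
  orientation-free, the observed behavior OB = sign(median(PD) −
  median(CN)), and Spearman correlations with clinical severity
  (UPDRS-III, UPDRS-III.I, H&Y) on PD subjects;
* **robustness adjudication**: a biomarker is *robust* when, within a task
  class (spontaneous speech SS, read passage RP, or text-dependent
  utterances TDU), (1) it is significant in at least two datasets, (2)
  every significant result shows the expected direction of change, and (3)
  every significant severity correlation has the matching sign;
* a **synthetic cohort generator** that renders 16 kHz audio plus annotated
  transcripts with plantable group effects (Cohen's-d shifts on generative
  parameters, Gaussian-copula severity links), because the clinical
  datasets this analysis design targets are access-restricted.

## Worked example

Adjudicate the packaged encoding of the published per-dataset result
tables (the package ships them as CSV fixtures):

```sh
robustmark adjudicate
```

prints

```json
{
 "robust": [
  "AUXCNT", "F0STD", "NOUNCNT", "NPCNT", "RHYSTD", "SENTCNT", "SILDUR",
  "SILPERC", "SILSPRAT", "SILTIME", "SILVAR", "SPTIME", "WORDCNT"
 ],
 "n_robust": 13,
 "significant_biomarkers_per_dataset": {
  "CzechPD": 7, "GITA": 4, "GermanPD": 15,
  "ItalianPVS": 9, "NLS": 9, "Neurovoz": 13
 }
}
```

— 13 of the 24 biomarkers meet all three robustness conditions: speech
time, pitch variability, the five pause measures, narrative length
(WORDCNT, SENTCNT), nouns, auxiliaries and noun phrases, and spontaneous
speech rhythm. Note that SPTIME qualifies through the spontaneous task
even though one dataset reverses it in repetition, and F1STD fails only
because its one significant severity correlation has the wrong sign —
exactly the distinctions the per-task-class conditions encode.

The statistics layer is usable on its own:

```python
>>> from robustmark import kruskal_wallis, eta_squared_from_h, auroc
>>> cn = [12.1, 9.8, 14.0, 11.2, 13.3]   # e.g. F0 SD in Hz, controls
>>> pd = [8.0, 7.4, 10.1, 6.9, 9.2]      # PD group: monopitch
>>> h, p = kruskal_wallis(cn, pd)
>>> print(f"H = {h:.2f}, p = {p:.4f}, eta2 = {eta_squared_from_h(h, 10, 2):.2f}, "
...       f"AUROC = {auroc(cn, pd):.2f}")
H = 5.77, p = 0.0163, eta2 = 0.60, AUROC = 0.96
```

An end-to-end synthetic run (simulate → extract → analyze):

```sh
robustmark simulate --config cohort.yaml --out-dir cohort/ --seed 4
robustmark extract  --manifest cohort/manifest.csv --out features.csv
robustmark analyze  --features features.csv --subjects cohort/manifest.csv \
                    --out-dir analysis/
```

where `cohort.yaml` lists datasets, group sizes, tasks and an effect plan
(`preset: table4` plants the full expected-behavior profile). `analyze`
writes `tests.csv` / `correlations.csv` with the reporting columns above,
`verdicts.csv` with the per-condition evidence, and `robust.json`.

## Layout

```
src/robustmark/
  audio.py        resampling, loudness, contours (F0/intensity/F1), energy VAD
  acoustic.py     contour SDs and pause statistics
  linguistic.py   CoNLL-U adapter, lexical/POS/phrase counts
  cognitive.py    rhythm variability, informational units, checklists
  stats.py        H-test, eta-squared, AUROC, BH-FDR, Spearman
  robustness.py   three-condition adjudication + packaged result tables
  synthetic.py    cohort generator (symbolic plan + audio rendering)
  pipeline.py     run_extract / run_analyze orchestration
  validation.py   calibration studies
  cli.py          robustmark simulate|extract|analyze|adjudicate
```

See `docs/methods.md` for the models, parameter choices, and known
limitations.
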