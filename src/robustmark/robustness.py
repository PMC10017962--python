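"""Cross-lingual robustness adjudication.

A biomarker is *robust* when, within some task class for which it has an
expected direction of change in PD:

1. it is significant (after FDR correction) in at least two distinct
   datasets;
2. every significant result in that task class shows the expected observed
   behavior; and
3. every significant severity correlation in that task class has the sign
   the expected direction implies (vacuously true with no significant
   correlations).

Conditions are evaluated per task class because two biomarkers (speech time
and rhythm variability) have opposite expected directions in spontaneous
versus reading-like tasks; a reversal in one task class says nothing about
language robustness in another.

The packaged fixture CSVs encode the expected-direction table and the
published per-dataset test/correlation tables, so the adjudicator can be run
on them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .stats import ALPHA

__all__ = [
    "ConfigurationError",
    "ExpectedBehavior",
    "RobustnessVerdict",
    "load_expected_behavior",
    "load_fixture_tests",
    "load_fixture_correlations",
    "adjudicate",
    "count_significant_per_dataset",
    "robust_set",
    "verdicts_to_frame",
]


class ConfigurationError(ValueError):
    """The expected-behavior table does not cover a tested biomarker/task."""


@dataclass(frozen=True)
class ExpectedBehavior:
    """Expected PD-vs-CN directions, per biomarker and task class.

    ``directions`` maps ``(biomarker, task_class)`` to 'up'/'down'; a task
    class of 'All' acts as a fallback for any task.
    """

    directions: dict[tuple[str, str], str]
    families: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpectedBehavior":
        directions = {}
        families = {}
        for row in df.itertuples():
            if row.direction not in ("up", "down"):
                raise ValueError(f"invalid direction {row.direction!r}")
            directions[(row.biomarker, row.task_class)] = row.direction
            if getattr(row, "family", None):
                families[row.biomarker] = row.family
        return cls(directions, families)

    def direction(self, biomarker: str, task: str) -> str:
        if (biomarker, task) in self.directions:
            return self.directions[(biomarker, task)]
        if (biomarker, "All") in self.directions:
            return self.directions[(biomarker, "All")]
        raise ConfigurationError(
            f"no expected direction for biomarker {biomarker!r} in task {task!r}"
        )

    def task_classes(self, biomarker: str, tasks) -> dict[str, str]:
        """Expected direction per concrete task class the biomarker was
        tested in."""
        return {t: self.direction(biomarker, t) for t in tasks}


@dataclass
class RobustnessVerdict:
    biomarker: str
    robust: bool
    datasets_significant: set[str]
    conditions: dict[str, dict]  # task class -> {cond1, cond2, cond3, pass, evidence}


def _fixture(name: str) -> pd.DataFrame:
    ref = resources.files("robustmark.data").joinpath(name)
    with ref.open(encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_expected_behavior() -> ExpectedBehavior:
    """The packaged expected-direction table."""
    return ExpectedBehavior.from_frame(_fixture("table4_expected.csv"))


def load_fixture_tests() -> pd.DataFrame:
    """The packaged per-dataset significant test results (acoustic +
    linguistic/cognitive)."""
    return pd.concat(
        [_fixture("table5_tests.csv"), _fixture("table6_tests.csv")],
        ignore_index=True,
    )


def load_fixture_correlations() -> pd.DataFrame:
    """The packaged significant severity correlations."""
    return _fixture("table7_correlations.csv")


def _significant_mask(df: pd.DataFrame, alpha: float) -> pd.Series:
    if "significant" in df.columns:
        return df["significant"].astype(bool)
    if "p_adj" in df.columns:
        return df["p_adj"] < alpha
    raise ValueError("results need a 'significant' or 'p_adj' column")


def adjudicate(
    expected: ExpectedBehavior,
    tests: pd.DataFrame,
    correlations: pd.DataFrame | None = None,
    alpha: float = ALPHA,
) -> dict[str, RobustnessVerdict]:
    """Apply the three robustness conditions to test/correlation results.

    ``tests`` needs columns dataset, task, biomarker, OB and either
    ``significant`` or ``p_adj``; ``correlations`` (optional) needs dataset,
    task, biomarker, rho and the same significance information.  Returns a
    verdict per biomarker name appearing in ``tests``.
    """
    tests = tests.copy()
    tests["_sig"] = _significant_mask(tests, alpha)
    if correlations is not None and len(correlations):
        correlations = correlations.copy()
        correlations["_sig"] = _significant_mask(correlations, alpha)

    verdicts: dict[str, RobustnessVerdict] = {}
    for biomarker, sub in tests.groupby("biomarker", sort=True):
        tasks = sorted(sub["task"].unique())
        per_class = expected.task_classes(biomarker, tasks)  # may raise
        conditions: dict[str, dict] = {}
        all_sig_datasets: set[str] = set()
        robust = False
        for task, direction in per_class.items():
            rows = sub[sub["task"] == task]
            sig = rows[rows["_sig"]]
            datasets = set(sig["dataset"])
            all_sig_datasets |= datasets
            cond1 = len(datasets) >= 2
            cond2 = bool((sig["OB"] == direction).all())
            cond3 = True
            corr_evidence = []
            if correlations is not None and len(correlations):
                cm = (
                    (correlations["biomarker"] == biomarker)
                    & (correlations["task"] == task)
                    & correlations["_sig"]
                )
                sig_corr = correlations[cm]
                if len(sig_corr):
                    want_positive = direction == "up"
                    cond3 = bool(
                        ((sig_corr["rho"] > 0) == want_positive).all()
                        and (sig_corr["rho"] != 0).all()
                    )
                    corr_evidence = sig_corr[["dataset", "scale", "rho"]].to_dict(
                        "records"
                    )
            passed = cond1 and cond2 and cond3
            robust = robust or passed
            conditions[task] = {
                "expected": direction,
                "cond1_two_datasets": cond1,
                "cond2_consistent_behavior": cond2,
                "cond3_correlation_sign": cond3,
                "pass": passed,
                "datasets_significant": sorted(datasets),
                "correlations": corr_evidence,
            }
        verdicts[biomarker] = RobustnessVerdict(
            biomarker, robust, all_sig_datasets, conditions
        )
    return verdicts


def count_significant_per_dataset(
    tests: pd.DataFrame, alpha: float = ALPHA
) -> dict[str, int]:
    """Distinct biomarker names significant in at least one task, per
    dataset."""
    if len(tests) == 0:
        return {}
    tests = tests.copy()
    tests["_sig"] = _significant_mask(tests, alpha)
    out: dict[str, int] = {}
    for dataset, sub in tests.groupby("dataset", sort=True):
        out[dataset] = sub.loc[sub["_sig"], "biomarker"].nunique()
    return out


def robust_set(verdicts: dict[str, RobustnessVerdict]) -> list[str]:
    return sorted(b for b, v in verdicts.items() if v.robust)


def verdicts_to_frame(verdicts: dict[str, RobustnessVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts.values():
        for task, cond in v.conditions.items():
            rows.append(
                {
                    "biomarker": v.biomarker,
                    "task": task,
                    "expected": cond["expected"],
                    "cond1": cond["cond1_two_datasets"],
                    "cond2": cond["cond2_consistent_behavior"],
                    "cond3": cond["cond3_correlation_sign"],
                    "class_pass": cond["pass"],
                    "robust": v.robust,
                    "datasets_significant": ";".join(cond["datasets_significant"]),
                }
            )
    return pd.DataFrame(rows)
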