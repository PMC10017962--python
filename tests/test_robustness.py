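"""Three-condition robustness adjudication, incl. on the published tables."""

import pandas as pd
import pytest

from robustmark.robustness import (
    ConfigurationError,
    ExpectedBehavior,
    adjudicate,
    count_significant_per_dataset,
    load_expected_behavior,
    load_fixture_correlations,
    load_fixture_tests,
    robust_set,
)

EXPECTED = ExpectedBehavior.from_frame(
    pd.DataFrame(
        [
            {"biomarker": "X", "task_class": "All", "direction": "up"},
            {"biomarker": "Y", "task_class": "SS", "direction": "down"},
        ]
    )
)


def trow(dataset, task="SS", biomarker="X", ob="up", sig=1):
    return {
        "dataset": dataset,
        "task": task,
        "biomarker": biomarker,
        "OB": ob,
        "significant": sig,
    }


class TestConditions:
    def test_two_datasets_consistent_is_robust(self):
        tests = pd.DataFrame([trow("A"), trow("B")])
        v = adjudicate(EXPECTED, tests)
        assert v["X"].robust

    def test_single_dataset_fails_condition_one(self):
        tests = pd.DataFrame([trow("A"), trow("B", sig=0)])
        v = adjudicate(EXPECTED, tests)
        assert not v["X"].robust
        assert not v["X"].conditions["SS"]["cond1_two_datasets"]

    def test_opposite_behaviors_fail_condition_two(self):
        tests = pd.DataFrame([trow("A"), trow("B", ob="down")])
        v = adjudicate(EXPECTED, tests)
        assert not v["X"].robust
        assert not v["X"].conditions["SS"]["cond2_consistent_behavior"]

    def test_wrong_correlation_sign_fails_condition_three(self):
        tests = pd.DataFrame([trow("A"), trow("B")])
        corrs = pd.DataFrame(
            [{"dataset": "A", "task": "SS", "biomarker": "X", "scale": "UPDRS-III",
              "rho": -0.5, "significant": 1}]
        )
        v = adjudicate(EXPECTED, tests, corrs)
        assert not v["X"].robust
        assert not v["X"].conditions["SS"]["cond3_correlation_sign"]

    def test_condition_three_vacuous_without_significant_correlations(self):
        tests = pd.DataFrame([trow("A"), trow("B")])
        corrs = pd.DataFrame(
            [{"dataset": "A", "task": "SS", "biomarker": "X", "scale": "UPDRS-III",
              "rho": -0.5, "significant": 0}]
        )
        v = adjudicate(EXPECTED, tests, corrs)
        assert v["X"].robust

    def test_per_task_class_adjudication(self):
        # robust via SS despite a reversal in another task class
        expected = ExpectedBehavior.from_frame(
            pd.DataFrame(
                [
                    {"biomarker": "X", "task_class": "SS", "direction": "down"},
                    {"biomarker": "X", "task_class": "TDU", "direction": "up"},
                ]
            )
        )
        tests = pd.DataFrame(
            [
                trow("A", "SS", ob="down"),
                trow("B", "SS", ob="down"),
                trow("C", "TDU", ob="down"),  # reversed vs TDU expectation
                trow("D", "TDU", ob="down"),
            ]
        )
        v = adjudicate(expected, tests)
        assert v["X"].robust
        assert not v["X"].conditions["TDU"]["pass"]

    def test_uncovered_biomarker_is_configuration_error(self):
        tests = pd.DataFrame([trow("A", biomarker="Z")])
        with pytest.raises(ConfigurationError):
            adjudicate(EXPECTED, tests)

    def test_adding_nonsignificant_result_never_changes_verdicts(self):
        tests = pd.DataFrame([trow("A"), trow("B", ob="down")])
        before = adjudicate(EXPECTED, tests)
        extra = pd.concat(
            [tests, pd.DataFrame([trow("C", ob="down", sig=0)])], ignore_index=True
        )
        after = adjudicate(EXPECTED, extra)
        assert {b: v.robust for b, v in before.items()} == {
            b: v.robust for b, v in after.items()
        }


class TestPublishedTables:
    def test_thirteen_robust_biomarkers(self):
        v = adjudicate(
            load_expected_behavior(), load_fixture_tests(), load_fixture_correlations()
        )
        assert robust_set(v) == sorted(
            [
                "SPTIME", "F0STD", "SILTIME", "SILPERC", "SILSPRAT", "SILDUR",
                "SILVAR", "WORDCNT", "SENTCNT", "NOUNCNT", "AUXCNT", "NPCNT",
                "RHYSTD",
            ]
        )

    def test_formant_variability_fails_on_correlation_sign(self):
        v = adjudicate(
            load_expected_behavior(), load_fixture_tests(), load_fixture_correlations()
        )
        assert not v["F1STD"].robust
        assert not v["F1STD"].conditions["TDU"]["cond3_correlation_sign"]

    def test_informational_units_fail_on_single_dataset(self):
        v = adjudicate(
            load_expected_behavior(), load_fixture_tests(), load_fixture_correlations()
        )
        assert not v["IU"].robust
        assert v["IU"].datasets_significant == {"Neurovoz"}

    def test_distinct_name_counts_per_dataset(self):
        counts = count_significant_per_dataset(load_fixture_tests())
        assert counts == {
            "GermanPD": 15,
            "Neurovoz": 13,
            "ItalianPVS": 9,
            "NLS": 9,
            "CzechPD": 7,
            "GITA": 4,
        }

    def test_empty_test_set(self):
        assert count_significant_per_dataset(pd.DataFrame()) == {}
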