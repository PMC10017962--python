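"""Cognitive biomarkers: speech-rhythm variability and informational units.

RHYSTD is the sample standard deviation of the intervals between consecutive
word onsets (not of the raw timestamps, which would grow with recording
length).  Word onsets are an input contract — they come from time anchors in
the transcript, produced upstream by forced alignment.

IU counts how many items of a picture-description checklist are mentioned at
least once (type counting, lemma-based): each checklist item is a set of
acceptable lemmas and matches when any of them occurs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "IUChecklist",
    "rhythm_std",
    "rhythm_std_fluent",
    "informational_units",
    "load_checklist",
    "builtin_checklist",
]


@dataclass
class IUChecklist:
    """Checklist of salient picture events, one lemma set per item."""

    task: str
    language: str
    items: list[frozenset[str]]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("checklist must contain at least one item")
        self.items = [frozenset(i) for i in self.items]
        if any(not i for i in self.items):
            raise ValueError("checklist items must be non-empty lemma sets")

    def __len__(self) -> int:
        return len(self.items)


def rhythm_std(onsets) -> float:
    """Sample SD of inter-onset intervals; NaN when fewer than 3 onsets.

    Onsets must be strictly increasing (word start times in seconds).
    """
    onsets = np.asarray(list(onsets), dtype=float)
    if len(onsets) >= 2 and not np.all(np.diff(onsets) > 0):
        raise ValueError("word onsets must be strictly increasing")
    if len(onsets) < 3:
        return float("nan")
    return float(np.std(np.diff(onsets), ddof=1))


def rhythm_std_fluent(onsets, segmentation=None, max_gap: float | None = None) -> float:
    """Rhythm variability over pause-free inter-onset intervals.

    Intervals whose two onsets fall in different speech intervals of
    ``segmentation`` (or whose length exceeds ``max_gap``) are excluded, so
    the measure reflects word-timing regularity within fluent runs rather
    than pausing, which the pause biomarkers already quantify.  Segment-wise
    word alignment produces exactly the within-run intervals.  NaN when
    fewer than 2 intervals survive.
    """
    onsets = np.asarray(list(onsets), dtype=float)
    if len(onsets) >= 2 and not np.all(np.diff(onsets) > 0):
        raise ValueError("word onsets must be strictly increasing")
    if len(onsets) < 3:
        return float("nan")
    intervals = np.diff(onsets)
    keep = np.ones(len(intervals), dtype=bool)
    if segmentation is not None:
        speech = [
            (s, e) for s, e, lab in segmentation.intervals if lab == "speech"
        ]

        def run_of(t: float) -> int:
            for i, (s, e) in enumerate(speech):
                if s <= t < e:
                    return i
            return -1

        runs = np.array([run_of(t) for t in onsets])
        keep &= (runs[:-1] == runs[1:]) & (runs[:-1] >= 0)
    if max_gap is not None:
        keep &= intervals <= max_gap
    if keep.sum() < 2:
        return float("nan")
    return float(np.std(intervals[keep], ddof=1))


def informational_units(lemmas, checklist: IUChecklist) -> int:
    """Number of checklist items with at least one acceptable lemma present."""
    present = set(lemmas)
    return sum(1 for item in checklist.items if item & present)


def load_checklist(path) -> IUChecklist:
    """Load a checklist JSON: ``{task, language, items: [[lemma, ...], ...]}``."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return IUChecklist(obj["task"], obj["language"], [frozenset(i) for i in obj["items"]])


def builtin_checklist(language: str) -> IUChecklist:
    """Packaged picture-description checklists (``en``: Cookie Theft, 13
    items; ``es``: 4 verb items)."""
    name = {"en": "iu_checklist_en.json", "es": "iu_checklist_es.json"}[language]
    ref = resources.files("robustmark.data").joinpath(name)
    with ref.open(encoding="utf-8") as fh:
        obj = json.load(fh)
    return IUChecklist(obj["task"], obj["language"], [frozenset(i) for i in obj["items"]])
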