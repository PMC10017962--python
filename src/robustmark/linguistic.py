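"""Linguistic biomarkers from annotated transcripts.

Transcripts arrive already annotated (Universal POS tags, sentence
boundaries, optional NP/VP/PP phrase spans and word-level time anchors) in
CoNLL-U; no tagging or parsing happens here.  Thirteen measures of lexical
and syntactic production are computed: word/sentence counts and lengths,
six POS-class counts, and three phrase-class counts.

The function-word class defaults to the closed Universal POS classes
{DET, PRON, ADP, CCONJ, SCONJ, PART, AUX, INTJ} and can be overridden per
language profile; an explicit ``Func=Yes``/``Func=No`` MISC key on a token
always wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Token",
    "AnnotatedTranscript",
    "MissingLayerError",
    "FUNCTION_WORD_UPOS",
    "read_conllu",
    "write_conllu",
    "read_phrase_spans_tsv",
    "lexical_counts",
    "pos_counts",
    "phrase_counts",
    "LINGUISTIC_FEATURE_NAMES",
]

FUNCTION_WORD_UPOS = frozenset(
    {"DET", "PRON", "ADP", "CCONJ", "SCONJ", "PART", "AUX", "INTJ"}
)

UPOS_INVENTORY = frozenset(
    "ADJ ADP ADV AUX CCONJ DET INTJ NOUN NUM PART PRON PROPN PUNCT SCONJ SYM VERB X".split()
)

POS_COUNT_CLASSES = ("NOUN", "VERB", "ADJ", "ADV", "NUM", "AUX")
PHRASE_LABELS = ("NP", "VP", "PP")

LINGUISTIC_FEATURE_NAMES = (
    "WORDCNT",
    "WORDLEN",
    "SENTCNT",
    "SENTLEN",
    "NOUNCNT",
    "VERBCNT",
    "ADJCNT",
    "ADVCNT",
    "NUMCNT",
    "AUXCNT",
    "NPCNT",
    "VPCNT",
    "PPCNT",
)


class MissingLayerError(ValueError):
    """An annotation layer required by a feature is absent."""


@dataclass
class Token:
    form: str
    lemma: str
    upos: str
    is_function_word: bool
    sent_index: int
    start: float | None = None
    end: float | None = None

    def __post_init__(self) -> None:
        if self.upos not in UPOS_INVENTORY:
            raise ValueError(f"unknown Universal POS tag {self.upos!r}")


@dataclass
class AnnotatedTranscript:
    """Tokens plus an optional phrase-span layer.

    ``phrase_spans`` is a list of ``(label, start_token, end_token)`` with an
    inclusive token range, or ``None`` when the layer was never produced
    (e.g., no parser exists for the language).
    """

    tokens: list[Token] = field(default_factory=list)
    phrase_spans: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        prev = -1
        for t in self.tokens:
            if t.sent_index < prev:
                raise ValueError("sentence indices must be non-decreasing")
            prev = t.sent_index
        if self.phrase_spans is not None:
            n = len(self.tokens)
            for label, a, b in self.phrase_spans:
                if label not in PHRASE_LABELS:
                    raise ValueError(f"unknown phrase label {label!r}")
                if not (0 <= a <= b < n):
                    raise ValueError("phrase span outside token range")

    @property
    def lemmas(self) -> list[str]:
        return [t.lemma for t in self.tokens]

    def word_onsets(self) -> list[float]:
        """Start times of time-anchored tokens, in transcript order."""
        return [t.start for t in self.tokens if t.start is not None]

    def __add__(self, other: "AnnotatedTranscript") -> "AnnotatedTranscript":
        offset = (self.tokens[-1].sent_index + 1) if self.tokens else 0
        shifted = [
            Token(t.form, t.lemma, t.upos, t.is_function_word,
                  t.sent_index + offset, t.start, t.end)
            for t in other.tokens
        ]
        spans = None
        if self.phrase_spans is not None and other.phrase_spans is not None:
            n = len(self.tokens)
            spans = list(self.phrase_spans) + [
                (lab, a + n, b + n) for lab, a, b in other.phrase_spans
            ]
        return AnnotatedTranscript(list(self.tokens) + shifted, spans)


# ---------------------------------------------------------------------------
# CoNLL-U I/O
#
# Standard 10-column lines; time anchors and chunk tags travel in MISC as
# StartTime=<s>|EndTime=<s>|Func=Yes|Chunk=B-NP.  Multiword-token and empty
# nodes (ids with '-' or '.') are skipped.


def _parse_misc(misc: str) -> dict[str, str]:
    if misc in ("_", ""):
        return {}
    out = {}
    for part in misc.split("|"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_conllu(
    path,
    function_upos: frozenset[str] = FUNCTION_WORD_UPOS,
) -> AnnotatedTranscript:
    """Read a CoNLL-U file into an ``AnnotatedTranscript``.

    The phrase layer is reconstructed from BIO ``Chunk=`` MISC tags when any
    token carries one; otherwise it is ``None`` (use
    :func:`read_phrase_spans_tsv` for sidecar span files).
    """
    tokens: list[Token] = []
    chunk_tags: list[str | None] = []
    sent_index = -1
    in_sentence = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                in_sentence = False
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ValueError(f"malformed CoNLL-U line: {line!r}")
            tid, form, lemma, upos = cols[0], cols[1], cols[2], cols[3]
            if "-" in tid or "." in tid:
                continue
            if not in_sentence:
                sent_index += 1
                in_sentence = True
            misc = _parse_misc(cols[9])
            if "Func" in misc:
                func = misc["Func"] == "Yes"
            else:
                func = upos in function_upos
            start = float(misc["StartTime"]) if "StartTime" in misc else None
            end = float(misc["EndTime"]) if "EndTime" in misc else None
            tokens.append(Token(form, lemma, upos, func, sent_index, start, end))
            chunk_tags.append(misc.get("Chunk"))
    spans = _spans_from_bio(chunk_tags) if any(chunk_tags) else None
    return AnnotatedTranscript(tokens, spans)


def _spans_from_bio(tags: list[str | None]) -> list[tuple[str, int, int]]:
    spans = []
    open_label, open_start = None, None
    for i, tag in enumerate(tags):
        if tag and tag.startswith("B-"):
            if open_label is not None:
                spans.append((open_label, open_start, i - 1))
            open_label, open_start = tag[2:], i
        elif tag and tag.startswith("I-") and open_label == tag[2:]:
            continue
        else:
            if open_label is not None:
                spans.append((open_label, open_start, i - 1))
                open_label, open_start = None, None
    if open_label is not None:
        spans.append((open_label, open_start, len(tags) - 1))
    return spans


def write_conllu(path, t: AnnotatedTranscript) -> None:
    """Write a transcript as CoNLL-U with MISC time anchors and chunk tags."""
    bio: list[str | None] = [None] * len(t.tokens)
    if t.phrase_spans is not None:
        # later spans overwrite on overlap; nested inner spans re-begin
        for label, a, b in t.phrase_spans:
            bio[a] = f"B-{label}"
            for i in range(a + 1, b + 1):
                bio[i] = f"I-{label}"
    with open(path, "w", encoding="utf-8") as fh:
        current_sent = None
        tid = 0
        for i, tok in enumerate(t.tokens):
            if tok.sent_index != current_sent:
                if current_sent is not None:
                    fh.write("\n")
                current_sent = tok.sent_index
                fh.write(f"# sent_id = {current_sent + 1}\n")
                tid = 0
            tid += 1
            misc_parts = []
            if tok.start is not None:
                misc_parts.append(f"StartTime={tok.start:.3f}")
            if tok.end is not None:
                misc_parts.append(f"EndTime={tok.end:.3f}")
            misc_parts.append(f"Func={'Yes' if tok.is_function_word else 'No'}")
            if bio[i] is not None:
                misc_parts.append(f"Chunk={bio[i]}")
            misc = "|".join(misc_parts) if misc_parts else "_"
            fh.write(
                f"{tid}\t{tok.form}\t{tok.lemma}\t{tok.upos}\t_\t_\t0\t_\t_\t{misc}\n"
            )
        fh.write("\n")


def read_phrase_spans_tsv(path) -> list[tuple[str, int, int]]:
    """Read a sidecar phrase-span file: ``label<TAB>start<TAB>end`` rows."""
    spans = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            label, a, b = line.rstrip("\n").split("\t")
            spans.append((label, int(a), int(b)))
    return spans


# ---------------------------------------------------------------------------
# Features


def lexical_counts(t: AnnotatedTranscript) -> dict[str, float]:
    """WORDCNT, WORDLEN, SENTCNT, SENTLEN.

    WORDCNT and WORDLEN are computed after function-word removal; SENTLEN is
    mean tokens per sentence over *all* tokens (function words carry
    sentence-structural information).  WORDLEN is NaN when no content words
    remain.
    """
    content = [tok for tok in t.tokens if not tok.is_function_word]
    sent_count = len({tok.sent_index for tok in t.tokens})
    return {
        "WORDCNT": float(len(content)),
        "WORDLEN": (
            sum(len(tok.form) for tok in content) / len(content)
            if content
            else float("nan")
        ),
        "SENTCNT": float(sent_count),
        "SENTLEN": len(t.tokens) / sent_count if sent_count else float("nan"),
    }


def pos_counts(t: AnnotatedTranscript) -> dict[str, float]:
    """Raw token counts for NOUN, VERB, ADJ, ADV, NUM, AUX."""
    counts = {c: 0 for c in POS_COUNT_CLASSES}
    for tok in t.tokens:
        if tok.upos in counts:
            counts[tok.upos] += 1
    return {f"{c}CNT": float(v) for c, v in counts.items()}


def phrase_counts(t: AnnotatedTranscript) -> dict[str, float]:
    """NPCNT, VPCNT, PPCNT — label-wise span counts (nested spans all count).

    Raises :class:`MissingLayerError` when the transcript has no phrase-span
    layer (the analysis is then skipped for that language, with a flag).
    """
    if t.phrase_spans is None:
        raise MissingLayerError("transcript has no phrase-span layer")
    counts = {lab: 0 for lab in PHRASE_LABELS}
    for label, _, _ in t.phrase_spans:
        counts[label] += 1
    return {f"{lab}CNT": float(v) for lab, v in counts.items()}
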