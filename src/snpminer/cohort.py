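"""Patient/control group-size and cohort-ethnicity extraction.

Group sizes: every numeric-modifier dependency whose dependent parses as an
integer becomes a candidate (its quantified head noun plus a window of two
tokens on each side of the number).  Candidates are matched against two
configurable keyword sets — patient-group words ("patient", "case",
"subject") and control-group words ("control", "normal", "healthy") —
first on the head token, then on the neighbor window.  Control keywords
outrank patient keywords when both hit one candidate, so "312 healthy
subjects" counts as controls even though "subjects" alone would read as
patients.  The first hit per set in abstract order wins, which selects
stated totals ("A total of 169 ED patients ...") over the subgroup
breakdowns that follow them.

Ethnicity: nationality-category (NORP) entity spans of at least a minimum
length are counted across the abstract; the most frequent label wins, ties
going to the earliest first occurrence.

Under a backend providing no dependency arcs, every integer token becomes
a head-less candidate and only the neighbor-window rule applies; phrases
whose keyword sits more than two tokens from the number ("889 lung cancer
cases") are then out of reach — a documented degradation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .nlp import NORP, NUMMOD, ParsedSentence, Token

DEFAULT_PATIENT_KEYWORDS: tuple[str, ...] = ("patient", "case", "subject")
DEFAULT_CONTROL_KEYWORDS: tuple[str, ...] = ("control", "normal", "healthy")
DEFAULT_MIN_NATIONALITY_LENGTH = 4

_INT_RE = re.compile(r"\d{1,3}(?:,\d{3})+|\d+")


@dataclass(frozen=True)
class NumericCandidate:
    value: int
    start: int
    end: int
    head: str                    # quantified head-token text; "" when unknown
    window: tuple[str, ...]      # up to 2 token texts on each side
    sentence_text: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("candidate value must be non-negative")


@dataclass(frozen=True)
class CohortInfo:
    patient_size: int | None = None
    control_size: int | None = None
    ethnicity: str | None = None
    patient_evidence: str | None = None
    control_evidence: str | None = None
    ethnicity_evidence: str | None = None


def _parse_int(token_text: str) -> int | None:
    if _INT_RE.fullmatch(token_text):
        return int(token_text.replace(",", ""))
    return None


def _window(tokens: tuple[Token, ...], i: int, radius: int = 2) -> tuple[str, ...]:
    lo = max(i - radius, 0)
    hi = min(i + radius + 1, len(tokens))
    return tuple(t.text for j, t in enumerate(tokens[lo:hi], lo) if j != i)


def collect_numeric_candidates(
    parsed: list[ParsedSentence],
) -> list[NumericCandidate]:
    """One candidate per integer-valued numeric modifier, in abstract order.

    Thousands separators are accepted ("1,005"); decimals are not group
    sizes and are rejected.  Sentences without dependency arcs contribute
    every integer token as a head-less candidate.
    """
    candidates = []
    for sent in parsed:
        if sent.arcs:
            for arc in sent.arcs:
                if arc.relation != NUMMOD:
                    continue
                tok = sent.tokens[arc.dependent]
                value = _parse_int(tok.text)
                if value is None:
                    continue
                candidates.append(
                    NumericCandidate(
                        value=value,
                        start=tok.start,
                        end=tok.end,
                        head=sent.tokens[arc.head].text,
                        window=_window(sent.tokens, tok.index),
                        sentence_text=sent.text,
                    )
                )
        else:
            for tok in sent.tokens:
                value = _parse_int(tok.text)
                if value is None:
                    continue
                candidates.append(
                    NumericCandidate(
                        value=value,
                        start=tok.start,
                        end=tok.end,
                        head="",
                        window=_window(sent.tokens, tok.index),
                        sentence_text=sent.text,
                    )
                )
    return candidates


def _stem(word: str) -> str:
    w = word.lower()
    if w.endswith("es") and len(w) > 4:
        w = w[:-2] if w.endswith(("ches", "shes", "sses", "xes")) else w[:-1]
    elif w.endswith("s") and len(w) > 3:
        w = w[:-1]
    return w


def _matches(word: str, keywords: tuple[str, ...]) -> bool:
    return word.lower() in keywords or _stem(word) in keywords


def match_group_sizes(
    candidates: list[NumericCandidate],
    patient_keywords: tuple[str, ...] = DEFAULT_PATIENT_KEYWORDS,
    control_keywords: tuple[str, ...] = DEFAULT_CONTROL_KEYWORDS,
) -> CohortInfo:
    """Assign candidates to patient/control groups; first hit per set wins.

    Keyword matching is case- and plural-insensitive; the head token is
    consulted first, then the neighbor window.  A candidate hitting both
    sets is a control (control keywords take precedence).
    """
    patient: NumericCandidate | None = None
    control: NumericCandidate | None = None
    for cand in candidates:
        p_hit = _matches(cand.head, patient_keywords) if cand.head else False
        c_hit = _matches(cand.head, control_keywords) if cand.head else False
        if not p_hit and not c_hit:
            p_hit = any(_matches(w, patient_keywords) for w in cand.window)
            c_hit = any(_matches(w, control_keywords) for w in cand.window)
        else:
            # head decided one set; the window may still reveal the other
            p_hit = p_hit or any(_matches(w, patient_keywords) for w in cand.window)
            c_hit = c_hit or any(_matches(w, control_keywords) for w in cand.window)
        if c_hit:
            if control is None:
                control = cand
        elif p_hit:
            if patient is None:
                patient = cand
        if patient is not None and control is not None:
            break
    return CohortInfo(
        patient_size=patient.value if patient else None,
        control_size=control.value if control else None,
        patient_evidence=patient.sentence_text if patient else None,
        control_evidence=control.sentence_text if control else None,
    )


def extract_ethnicity(
    parsed: list[ParsedSentence],
    min_length: int = DEFAULT_MIN_NATIONALITY_LENGTH,
) -> tuple[str | None, str | None]:
    """Most frequent nationality label across the abstract, with evidence.

    Labels shorter than ``min_length`` are discarded (acronym noise);
    counting is case-insensitive over the normalized label; ties break to
    the earliest first occurrence.  Returns (label, evidence sentence) or
    (None, None).
    """
    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    surface: dict[str, str] = {}
    evidence: dict[str, str] = {}
    order = 0
    for sent in parsed:
        for ent in sent.entities:
            if ent.category != NORP or len(ent.text) < min_length:
                continue
            label = ent.text.lower()
            counts[label] = counts.get(label, 0) + 1
            if label not in first_seen:
                first_seen[label] = order
                surface[label] = ent.text
                evidence[label] = sent.text
            order += 1
    if not counts:
        return None, None
    winner = min(counts, key=lambda lab: (-counts[lab], first_seen[lab]))
    return surface[winner], evidence[winner]


def extract_cohort(
    parsed: list[ParsedSentence],
    patient_keywords: tuple[str, ...] = DEFAULT_PATIENT_KEYWORDS,
    control_keywords: tuple[str, ...] = DEFAULT_CONTROL_KEYWORDS,
    min_nationality_length: int = DEFAULT_MIN_NATIONALITY_LENGTH,
) -> CohortInfo:
    """Full per-abstract cohort summary: sizes plus ethnicity."""
    sizes = match_group_sizes(
        collect_numeric_candidates(parsed), patient_keywords, control_keywords
    )
    ethnicity, ethnicity_evidence = extract_ethnicity(parsed, min_nationality_length)
    return CohortInfo(
        patient_size=sizes.patient_size,
        control_size=sizes.control_size,
        ethnicity=ethnicity,
        patient_evidence=sizes.patient_evidence,
        control_evidence=sizes.control_evidence,
        ethnicity_evidence=ethnicity_evidence,
    )
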