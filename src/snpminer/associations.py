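"""Result-sentence flagging, statistic parsing, and SNP-value pairing.

GWAS abstracts report the same statistic in many typographic dialects:

    P = 3.54 × 10(−18)      P = 2.67 ×10^−9      P=4.74e-20
    combined P = 4.4 × 10(−7)        P-trend < 0.001      OR = 1.79

Sentences are therefore normalized before parsing: exponent dialects are
rewritten to e-notation first (so their brackets survive as part of the
number), then quotes and brackets are stripped, then the many P-value
marker spellings are collapsed to the single canonical marker "P".  Every
edit is tracked in an offset map so each parsed value can be traced back to
its span in the original sentence — pairing distances and evidence text
always refer to the un-normalized sentence.

Pairing follows two rules.  When a sentence carries exactly one pairable
value of a kind and any number of SNPs, the value is broadcast to every
SNP.  Otherwise each SNP group, in first-occurrence order, consumes the
nearest not-yet-consumed value (character distance between closest span
edges, minimized over the group's mention spans; ties prefer the value
following the SNP, reflecting the dominant "rsID, P = ..." reporting
style).  Threshold statements such as "P ≤ 5.0 × 10(−8)" are recognized
but never enter the pairing pool.  P and odds-ratio pairing run the same
procedure over separate consumption pools.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

from .nlp import ParsedSentence
from .snps import SnpGroup, dedupe_mentions, find_snp_mentions

logger = logging.getLogger(__name__)

KIND_P = "P"
KIND_OR = "OR"

# canonical comparator spellings
_CMP_CANON = {
    "=": "=", "==": "=", "of": "=", "was": "=", "is": "=",
    "<": "<", "≤": "≤", "<=": "≤", "=<": "≤",
    ">": ">", "≥": "≥", ">=": "≥", "=>": "≥",
}

# mantissa ×10 exponent, in caret, parenthesis, or bare signed form;
# U+2212 (minus), en-dash and hyphen-minus all act as negative signs
_EXPONENT_RE = re.compile(
    r"(?P<mant>\d+(?:\.\d+)?)\s*[×xX*]\s*10"
    r"(?:\s*(?:\^|\*\*)\s*\(?\s*(?P<exp1>[+\-−–]?\d+)\s*\)?\s*\^?"
    r"|\s*\(\s*(?P<exp2>[+\-−–]?\d+)\s*\)"
    r"|(?P<exp3>[+\-−–]\d+))"
)

# e-notation written with a typographic minus ("3.5e−18")
_ESIGN_RE = re.compile(r"(?<=[0-9][eE])[−–](?=\d)")

_STRIP_RE = re.compile(r"[\"'“”‘’()\[\]{}]")

# default P-marker spellings collapsed to canonical "P"; config-extensible
DEFAULT_P_MARKERS: tuple[str, ...] = (
    "P-value", "P-values", "P value", "P values", "Pvalue", "Pvalues",
    "P-val", "P-combine", "P-combined", "combined P", "P-meta", "meta P",
    "Pmeta", "P-trend", "Ptrend", "P-corrected", "corrected P", "P-adjusted",
    "adjusted P",
)

# number after normalization: requires a decimal point or an exponent so
# that counts, years and thousands-grouped integers are never P/OR values
_NUMBER = r"(?:\d+\.\d+(?:[eE][-+]?\d+)?|\d+[eE][-+]?\d+)"

_P_VALUE_RE = re.compile(
    rf"(?<![A-Za-z0-9])P\s*"
    rf"(?:(?P<cmp><=|>=|=<|=>|[=<>≤≥])|(?P<word>of|was|is)\s)?\s*"
    rf"(?P<num>{_NUMBER})"
)
_OR_VALUE_RE = re.compile(
    rf"(?<![A-Za-z0-9])(?:ORs?|[Oo]dds\s+[Rr]atios?)\s*"
    rf"(?:(?P<cmp><=|>=|=<|=>|[=<>≤≥])|(?P<word>of|was|is)\s)?\s*"
    rf"(?P<num>{_NUMBER})"
)


@dataclass(frozen=True)
class StatValue:
    kind: str                 # KIND_P or KIND_OR
    comparator: str           # one of = < ≤ > ≥
    value: float
    surface: str              # slice of the ORIGINAL sentence
    start: int                # offsets into the original sentence
    end: int
    is_threshold: bool

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("statistic values must be positive")

    def canonical(self) -> str:
        return f"{self.kind} {self.comparator} {self.value!r}"


@dataclass(frozen=True)
class AssociationPair:
    rsid: str
    p_value: StatValue | None
    or_value: StatValue | None
    evidence_sentence: str
    pmid: str

    def __post_init__(self) -> None:
        if self.p_value is None and self.or_value is None:
            raise ValueError("association pair needs a P-value or an OR")


@dataclass(frozen=True)
class NormalizedSentence:
    """A normalized sentence plus a per-character map to the original."""

    text: str
    regions: tuple[tuple[int, int], ...]  # per normalized char: source span
    original: str

    def to_original(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open span of the normalized text back to the original."""
        if start >= end:
            raise ValueError("empty span")
        return self.regions[start][0], self.regions[end - 1][1]


def _apply_edit(
    text: str,
    regions: list[tuple[int, int]],
    pattern: re.Pattern[str],
    render,
) -> tuple[str, list[tuple[int, int]]]:
    """Rewrite every match of ``pattern``; each replacement character maps
    to the whole consumed source region."""
    out: list[str] = []
    out_regions: list[tuple[int, int]] = []
    pos = 0
    for m in pattern.finditer(text):
        out.append(text[pos:m.start()])
        out_regions.extend(regions[pos:m.start()])
        replacement = render(m)
        if replacement:
            src = (regions[m.start()][0], regions[m.end() - 1][1])
            out.append(replacement)
            out_regions.extend([src] * len(replacement))
        pos = m.end()
    out.append(text[pos:])
    out_regions.extend(regions[pos:])
    return "".join(out), out_regions


def _sign(ch: str) -> str:
    return "-" if ch in "−–-" else "+"


def _render_exponent(m: re.Match[str]) -> str:
    exp = next(g for g in (m["exp1"], m["exp2"], m["exp3"]) if g is not None)
    if exp[0] in "+-−–":
        exp = _sign(exp[0]) + exp[1:]
    return f"{m['mant']}e{exp}"


def _marker_pattern(variants: tuple[str, ...]) -> re.Pattern[str]:
    alts = sorted(variants, key=len, reverse=True)
    body = "|".join(re.escape(v).replace(r"\ ", r"\s+") for v in alts)
    return re.compile(rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])", re.IGNORECASE)


_LOWER_P_RE = re.compile(r"(?<![A-Za-z0-9])p(?![A-Za-z0-9])")


def normalize_sentence(
    sentence: str,
    p_markers: tuple[str, ...] = DEFAULT_P_MARKERS,
) -> NormalizedSentence:
    """Rewrite a sentence into the canonical statistic dialect.

    Stages, in order: exponent dialects → e-notation (before any bracket
    stripping, so "10(−18)" is still intact); typographic minus inside
    e-notation → "-"; quotes/brackets removed; P-marker variants and the
    bare lowercase "p" token → canonical "P".
    """
    text = sentence
    regions = [(i, i + 1) for i in range(len(text))]
    text, regions = _apply_edit(text, regions, _EXPONENT_RE, _render_exponent)
    text, regions = _apply_edit(text, regions, _ESIGN_RE, lambda m: "-")
    text, regions = _apply_edit(text, regions, _STRIP_RE, lambda m: "")
    text, regions = _apply_edit(text, regions, _marker_pattern(p_markers), lambda m: "P")
    text, regions = _apply_edit(text, regions, _LOWER_P_RE, lambda m: "P")
    return NormalizedSentence(text=text, regions=tuple(regions), original=sentence)


def parse_number(text: str) -> float:
    """Parse a number written in any supported dialect.

    Accepts plain decimals, e-notation, caret and parenthesized exponent
    forms, with Unicode minus, en-dash or hyphen-minus signs.  Raises
    ``ValueError`` when no number is found.
    """
    norm = normalize_sentence(text)
    m = re.search(_NUMBER + r"|\d+", norm.text)
    if m is None:
        raise ValueError(f"no parseable number in {text!r}")
    return float(m.group())


def parse_stat_values(
    norm: NormalizedSentence,
    p_markers: tuple[str, ...] = DEFAULT_P_MARKERS,  # noqa: ARG001 (API symmetry)
) -> list[StatValue]:
    """Extract every marker-bound P and OR value from a normalized sentence.

    Only numbers bound to a marker are extracted: in "P = 0.045 and 0.032"
    the bare 0.032 yields nothing.  Threshold flags are resolved per
    sentence: a "≤"/"<"-comparator value is a threshold, except that "<"
    stays pairable when no "="-comparator value of the same kind coexists
    (abstracts reporting a lone "P < 0.001" mean the association's value).
    """
    raw: list[tuple[str, str, float, int, int]] = []
    for kind, pattern in ((KIND_P, _P_VALUE_RE), (KIND_OR, _OR_VALUE_RE)):
        for m in pattern.finditer(norm.text):
            cmp_txt = m["cmp"] or m["word"] or "="
            comparator = _CMP_CANON[cmp_txt]
            try:
                value = float(m["num"])
            except ValueError:  # pragma: no cover - grammar precludes it
                logger.warning("unparseable number %r skipped", m["num"])
                continue
            if value <= 0:
                logger.warning("non-positive %s value %r skipped", kind, m["num"])
                continue
            start, end = norm.to_original(m.start("num"), m.end("num"))
            raw.append((kind, comparator, value, start, end))

    values = []
    for kind, comparator, value, start, end in raw:
        if comparator == "≤":
            threshold = True
        elif comparator == "<":
            threshold = any(
                k == kind and c == "=" for k, c, _v, _s, _e in raw
            )
        else:
            threshold = False
        if kind == KIND_P and value > 1:
            logger.warning("P-value %g > 1 parsed from %r", value, norm.original)
        values.append(
            StatValue(
                kind=kind,
                comparator=comparator,
                value=value,
                surface=norm.original[start:end],
                start=start,
                end=end,
                is_threshold=threshold,
            )
        )
    values.sort(key=lambda v: (v.start, v.kind))
    return values


def find_result_sentences(sentences: list[ParsedSentence]) -> list[ParsedSentence]:
    """Keep the sentences that report a P-value: a canonical P marker bound
    to a parseable number.  Order is preserved."""
    flagged = []
    for sent in sentences:
        values = parse_stat_values(normalize_sentence(sent.text))
        if any(v.kind == KIND_P for v in values):
            flagged.append(sent)
    return flagged


def _span_distance(span: tuple[int, int], value: StatValue) -> tuple[int, bool]:
    """Character distance between nearest edges, and whether the value
    follows the span."""
    if value.start >= span[1]:
        return value.start - span[1], True
    if value.end <= span[0]:
        return span[0] - value.end, False
    return 0, True  # overlapping spans: treat as following


def pair_snps_to_values(
    snp_groups: list[SnpGroup],
    values: list[StatValue],
) -> list[tuple[str, StatValue]]:
    """Couple SNP groups to statistic values of one kind within a sentence.

    Broadcast rule: exactly one pairable value and at least one SNP — every
    SNP group receives it.  Otherwise nearest-unconsumed: groups iterate in
    first-occurrence order and each consumes its closest remaining value;
    a consumed value is unavailable to later groups, and groups left
    without a value yield no pair.
    """
    pool = sorted(
        (v for v in values if not v.is_threshold), key=lambda v: v.start
    )
    if not pool or not snp_groups:
        return []
    if len(pool) == 1:
        return [(g.rsid, pool[0]) for g in snp_groups]

    pairs = []
    consumed: set[int] = set()
    for group in snp_groups:
        best_i = None
        best_key: tuple[int, int, int] | None = None
        for i, value in enumerate(pool):
            if i in consumed:
                continue
            dist, follows = min(
                (_span_distance(span, value) for span in group.spans),
                key=lambda df: (df[0], not df[1]),
            )
            key = (dist, 0 if follows else 1, value.start)
            if best_key is None or key < best_key:
                best_key, best_i = key, i
        if best_i is not None:
            consumed.add(best_i)
            pairs.append((group.rsid, pool[best_i]))
    return pairs


def extract_associations(
    pmid: str,
    parsed: list[ParsedSentence],
    p_markers: tuple[str, ...] = DEFAULT_P_MARKERS,
) -> list[AssociationPair]:
    """Run the full within-sentence extraction over a parsed abstract.

    For each result sentence: recognize and dedupe rsID mentions, parse
    statistics, pair P values and OR values independently (separate
    consumption pools), and merge per rsid into association pairs carrying
    the original sentence as evidence.
    """
    out = []
    for sent in parsed:
        values = parse_stat_values(normalize_sentence(sent.text, p_markers))
        if not any(v.kind == KIND_P for v in values):
            continue
        groups = dedupe_mentions(find_snp_mentions(sent.text))
        if not groups:
            continue
        p_pairs = dict(
            pair_snps_to_values(groups, [v for v in values if v.kind == KIND_P])
        )
        or_pairs = dict(
            pair_snps_to_values(groups, [v for v in values if v.kind == KIND_OR])
        )
        unpaired = [
            v for v in values
            if not v.is_threshold
            and v not in p_pairs.values()
            and v not in or_pairs.values()
        ]
        if unpaired:
            logger.debug(
                "pmid %s: %d value(s) left unpaired in %r",
                pmid, len(unpaired), sent.text[:60],
            )
        for group in groups:
            p = p_pairs.get(group.rsid)
            o = or_pairs.get(group.rsid)
            if p is None and o is None:
                continue
            out.append(
                AssociationPair(
                    rsid=group.rsid,
                    p_value=p,
                    or_value=o,
                    evidence_sentence=sent.text,
                    pmid=pmid,
                )
            )
    return out


def values_close(a: float, b: float, rel_tol: float = 1e-6) -> bool:
    """Relative float comparison shared by the scorer and table round-trips."""
    return math.isclose(a, b, rel_tol=rel_tol, abs_tol=0.0)
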