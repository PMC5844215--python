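"""Linguistic-analysis contract consumed by the extraction pipeline.

The extractors never talk to a concrete parser; they consume the small
surface defined here — sentences, tokens, numeric-modifier dependency arcs
and nationality (NORP) entity spans — so any backend honouring the contract
can drive them.  Two deterministic backends ship with the package:

``heuristic`` (default)
    Rule sentence splitter and tokenizer, plus a token-level approximation
    of numeric-modifier dependencies (a number attaches to the terminal of
    the contiguous content-word run that follows it, falling back to a
    nearby content word on the left) and lexicon-based nationality entity
    tagging.  This is what cohort-size and ethnicity extraction use.

``rule_fallback``
    The same splitter/tokenizer with no arcs and no entities.  Stages that
    are pure text processing (rsID recognition, statistic parsing, pairing)
    behave identically under it; cohort matching degrades to the
    neighbor-window rule alone.

All character offsets are 0-based, half-open, and index into the ORIGINAL
abstract string, so ``abstract[t.start:t.end] == t.text`` always holds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .nationalities import is_nationality_token

NUMMOD = "nummod"
NORP = "NORP"


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty token span ({self.start}, {self.end})")


@dataclass(frozen=True)
class DependencyArc:
    """``dependent`` and ``head`` are token indices within one sentence."""

    dependent: int
    head: int
    relation: str

    def __post_init__(self) -> None:
        if self.dependent == self.head:
            raise ValueError("dependency arc may not be reflexive")


@dataclass(frozen=True)
class EntitySpan:
    text: str
    category: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty entity span")
        if not self.category:
            raise ValueError("entity category must be non-empty")


@dataclass(frozen=True)
class ParsedSentence:
    text: str
    start: int
    end: int
    tokens: tuple[Token, ...] = ()
    arcs: tuple[DependencyArc, ...] = ()
    entities: tuple[EntitySpan, ...] = ()


# ---------------------------------------------------------------------------
# tokenization / sentence splitting shared by both backends

# thousands-grouped integer | number | hyphenated word | single symbol
_TOKEN_RE = re.compile(
    r"\d{1,3}(?:,\d{3})+"
    r"|\d+(?:\.\d+)?"
    r"|[A-Za-z]+(?:[-'’][A-Za-z0-9]+)*"
    r"|[^\sA-Za-z0-9]"
)

# split after terminal punctuation followed by whitespace and an
# uppercase/digit sentence opener; decimal points never qualify because no
# whitespace follows them
_SENT_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+(?=[\"'(\[]?[A-Z0-9])")

# closed-class words that terminate a content-word run after a number
_RUN_STOPWORDS = frozenset(
    """a an the and or but with without of in on at by for to from as than
    versus vs were was is are be been being had have has using consisting
    including comprising recruited enrolled genotyped analyzed analysed
    studied examined respectively that who which whom whose this these those
    not no while whereas per among between during after before we they it
    our their its""".split()
)


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    pos = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        spans.append((pos, m.start()))
        pos = m.end()
    if pos < len(text):
        spans.append((pos, len(text)))
    # trim leading/trailing whitespace into the inter-sentence gaps
    trimmed = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            trimmed.append((s, e))
    return trimmed


def _tokenize(text: str, offset: int) -> tuple[Token, ...]:
    return tuple(
        Token(m.group(), offset + m.start(), offset + m.end(), i)
        for i, m in enumerate(_TOKEN_RE.finditer(text))
    )


def _is_integer_token(tok: Token) -> bool:
    return bool(re.fullmatch(r"\d{1,3}(?:,\d{3})+|\d+", tok.text))


def _is_content_word(tok: Token) -> bool:
    return tok.text[0].isalpha() and tok.text.lower() not in _RUN_STOPWORDS


class RuleFallbackBackend:
    """Minimal contract backend: sentences and tokens only."""

    name = "rule_fallback"

    def analyze(self, abstract_text: str) -> list[ParsedSentence]:
        if not abstract_text:
            return []
        sentences = []
        for s, e in _sentence_spans(abstract_text):
            sentences.append(
                ParsedSentence(
                    text=abstract_text[s:e],
                    start=s,
                    end=e,
                    tokens=_tokenize(abstract_text[s:e], s),
                )
            )
        return sentences


class HeuristicBackend(RuleFallbackBackend):
    """Adds numeric-modifier arcs and nationality entities on top of the
    rule splitter/tokenizer.

    The numeric-modifier approximation: for each integer token, the head is
    the last token of the contiguous content-word run immediately to its
    right (at most ``max_run`` tokens, stopping at closed-class words,
    punctuation or numbers) — e.g. in "889 lung cancer cases" the head of
    "889" is "cases".  When no run exists, the nearest content word within
    two tokens to the left is used ("controls (n = 1005)").  Numbers with
    neither get no arc.
    """

    name = "heuristic"
    max_run = 4

    def analyze(self, abstract_text: str) -> list[ParsedSentence]:
        sentences = super().analyze(abstract_text)
        out = []
        for sent in sentences:
            arcs = self._numeric_modifier_arcs(sent.tokens)
            ents = self._nationality_entities(sent.tokens)
            out.append(
                ParsedSentence(
                    text=sent.text,
                    start=sent.start,
                    end=sent.end,
                    tokens=sent.tokens,
                    arcs=arcs,
                    entities=ents,
                )
            )
        return out

    def _numeric_modifier_arcs(
        self, tokens: tuple[Token, ...]
    ) -> tuple[DependencyArc, ...]:
        arcs = []
        for tok in tokens:
            if not _is_integer_token(tok):
                continue
            head = self._head_right(tokens, tok.index)
            if head is None:
                head = self._head_left(tokens, tok.index)
            if head is not None:
                arcs.append(DependencyArc(tok.index, head, NUMMOD))
        return tuple(arcs)

    def _head_right(self, tokens: tuple[Token, ...], i: int) -> int | None:
        head = None
        for j in range(i + 1, min(i + 1 + self.max_run, len(tokens))):
            if _is_content_word(tokens[j]):
                head = j
            else:
                break
        return head

    def _head_left(self, tokens: tuple[Token, ...], i: int) -> int | None:
        for j in range(i - 1, max(i - 3, -1), -1):
            if _is_content_word(tokens[j]):
                return j
        return None

    def _nationality_entities(
        self, tokens: tuple[Token, ...]
    ) -> tuple[EntitySpan, ...]:
        return tuple(
            EntitySpan(tok.text, NORP, tok.start, tok.end)
            for tok in tokens
            if is_nationality_token(tok.text)
        )


_BACKENDS = {
    HeuristicBackend.name: HeuristicBackend,
    RuleFallbackBackend.name: RuleFallbackBackend,
}


def get_backend(name: str = "heuristic") -> RuleFallbackBackend:
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(
            f"unknown NLP backend {name!r}; expected one of {sorted(_BACKENDS)}"
        ) from None


def analyze(abstract_text: str, backend: str = "heuristic") -> list[ParsedSentence]:
    """Split, tokenize and annotate an abstract with the named backend."""
    return get_backend(backend).analyze(abstract_text)
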