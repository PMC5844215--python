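"""Recognition and normalization of dbSNP refSNP (rsID) mentions.

An rsID is "rs" followed by digits.  Mentions are matched
case-insensitively, with at most one space between the prefix and the
digits ("rs 123" occurs in print), and may carry a single trailing
reference/alternative-allele letter (G, C, T or A) glued to the digits, as
in "rs7086803C"; the letter is captured separately and stripped from the
normalized id.  A bracketed allele ("rs5770917[C]") is not part of the
mention.  Submitted-SNP ids ("ss...") are deliberately not matched: they
name unvalidated submissions, not reference clusters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_ALLELES = frozenset("ACGT")

# prefix not preceded by a letter/digit (avoids "Mrs 5", "XRS12");
# optional single space; digits; optional allele letter bound to the digits
# and followed by a non-alphanumeric boundary so gene symbols are not chewed
_RSID_RE = re.compile(
    r"(?<![A-Za-z0-9])([rR][sS]) ?([0-9]+)([GCTAgcta](?![A-Za-z0-9]))?"
)


@dataclass(frozen=True)
class SnpMention:
    surface: str
    rsid: str
    allele: str | None
    start: int
    end: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"rs[0-9]+", self.rsid):
            raise ValueError(f"malformed normalized rsid: {self.rsid!r}")
        if self.allele is not None and self.allele not in _ALLELES:
            raise ValueError(f"allele must be one of ACGT, got {self.allele!r}")


@dataclass(frozen=True)
class SnpGroup:
    """All mentions of one rsid within a sentence, in occurrence order."""

    rsid: str
    mentions: tuple[SnpMention, ...]

    @property
    def spans(self) -> tuple[tuple[int, int], ...]:
        return tuple((m.start, m.end) for m in self.mentions)


def find_snp_mentions(text: str) -> list[SnpMention]:
    """Return all rsID mentions in ``text``, ordered by start offset.

    Pure text processing — identical under every NLP backend.
    """
    mentions = []
    for m in _RSID_RE.finditer(text):
        allele = m.group(3)
        mentions.append(
            SnpMention(
                surface=m.group(0),
                rsid="rs" + m.group(2),
                allele=allele.upper() if allele else None,
                start=m.start(),
                end=m.end(),
            )
        )
    return mentions


def dedupe_mentions(mentions: list[SnpMention]) -> list[SnpGroup]:
    """Group mentions of the same rsid (one sentence's worth).

    Group order follows each rsid's first occurrence; a group keeps every
    span so downstream distance measures can take the minimum over them.
    """
    order: dict[str, list[SnpMention]] = {}
    for m in mentions:
        order.setdefault(m.rsid, []).append(m)
    return [SnpGroup(rsid, tuple(ms)) for rsid, ms in order.items()]
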