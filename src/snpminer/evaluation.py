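"""Scoring of predicted associations against gold annotations.

A prediction matches a gold annotation when PMID and rsID agree and every
statistic the gold record states (P-value, odds ratio, or both) is present
in the prediction within a relative tolerance.  Matching is one-to-one:
gold records are visited in order and greedily claim the first unmatched
compatible prediction.  Unmatched predictions are false positives,
unmatched gold records false negatives, and precision/recall/F1 follow.
Requiring value agreement — not mere (PMID, rsID) co-occurrence — means a
SNP coupled to the wrong number scores as an error, which is how missed
and mis-paired values show up in recall.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .associations import parse_number, values_close
from .report import AssociationRecord

GOLD_HEADER = ("pmid", "rsid", "p_value", "or_value", "sentence_id")


class GoldFormatError(ValueError):
    """Malformed gold annotation input; message names the line."""


@dataclass(frozen=True)
class GoldAnnotation:
    pmid: str
    rsid: str
    p_value: float | None = None
    or_value: float | None = None
    sentence_id: int | None = None

    def __post_init__(self) -> None:
        if self.p_value is None and self.or_value is None:
            raise ValueError("gold annotation needs a P-value or an OR")


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _gold_float(cell: str, lineno: int, column: str) -> float | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return parse_number(cell)
    except ValueError as exc:
        raise GoldFormatError(f"line {lineno}: bad {column} {cell!r}") from exc


def read_gold(
    source: str | Path | io.TextIOBase,
    dialect: str = "tsv",
) -> list[GoldAnnotation]:
    """Read gold annotations in the TSV dialect or a minimal XML layout.

    TSV: header ``pmid  rsid  p_value  or_value  sentence_id``; numeric
    cells use the same number grammar as the extractor, so exponent
    dialects are legal in gold files too.

    XML (``snpphena_xml``): a best-effort adapter for corpus-style files —
    ``<corpus><abstract pmid=...><association rsid=... p_value=...
    or_value=... sentence_id=.../></abstract></corpus>``.  The published
    corpus schema is not normative here; TSV is the contract-bearing form.
    """
    if dialect == "tsv":
        return _read_gold_tsv(source)
    if dialect == "snpphena_xml":
        return _read_gold_xml(source)
    raise ValueError(f"unknown gold dialect {dialect!r}")


def _read_gold_tsv(source) -> list[GoldAnnotation]:
    own = isinstance(source, (str, Path))
    stream = open(source, encoding="utf-8", newline="") if own else source
    try:
        reader = csv.reader(stream, delimiter="\t")
        try:
            header = tuple(next(reader))
        except StopIteration:
            raise GoldFormatError("line 1: empty gold file") from None
        if header != GOLD_HEADER:
            raise GoldFormatError(f"line 1: expected header {GOLD_HEADER}, got {header}")
        gold = []
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(GOLD_HEADER):
                raise GoldFormatError(f"line {lineno}: expected {len(GOLD_HEADER)} fields")
            pmid, rsid, p_cell, or_cell, sid_cell = row
            p_value = _gold_float(p_cell, lineno, "p_value")
            or_value = _gold_float(or_cell, lineno, "or_value")
            if p_value is None and or_value is None:
                raise GoldFormatError(
                    f"line {lineno}: annotation needs a p_value or an or_value"
                )
            try:
                gold.append(
                    GoldAnnotation(
                        pmid=pmid.strip(),
                        rsid=rsid.strip(),
                        p_value=p_value,
                        or_value=or_value,
                        sentence_id=int(sid_cell) if sid_cell.strip() else None,
                    )
                )
            except ValueError as exc:
                raise GoldFormatError(f"line {lineno}: {exc}") from exc
        return gold
    finally:
        if own:
            stream.close()


def _read_gold_xml(source) -> list[GoldAnnotation]:
    if isinstance(source, (str, Path)):
        tree = etree.parse(str(source))
    else:
        data = source.read()
        tree = etree.fromstring(data.encode() if isinstance(data, str) else data)
    gold = []
    for abstract in tree.iter("abstract"):
        pmid = abstract.get("pmid", "")
        for assoc in abstract.iter("association"):
            p_raw = assoc.get("p_value")
            or_raw = assoc.get("or_value")
            sid = assoc.get("sentence_id")
            gold.append(
                GoldAnnotation(
                    pmid=pmid,
                    rsid=assoc.get("rsid", ""),
                    p_value=parse_number(p_raw) if p_raw else None,
                    or_value=parse_number(or_raw) if or_raw else None,
                    sentence_id=int(sid) if sid else None,
                )
            )
    return gold


def write_gold_tsv(gold: list[GoldAnnotation]) -> str:
    """Render annotations in the TSV dialect (round-trips with read_gold)."""
    lines = ["\t".join(GOLD_HEADER)]
    for g in gold:
        lines.append(
            "\t".join(
                (
                    g.pmid,
                    g.rsid,
                    repr(g.p_value) if g.p_value is not None else "",
                    repr(g.or_value) if g.or_value is not None else "",
                    str(g.sentence_id) if g.sentence_id is not None else "",
                )
            )
        )
    return "\n".join(lines) + "\n"


def _compatible(
    pred: AssociationRecord, gold: GoldAnnotation, rel_tol: float
) -> bool:
    if pred.pmid != gold.pmid or pred.rsid != gold.rsid:
        return False
    if gold.p_value is not None:
        if pred.p_value is None or not values_close(pred.p_value, gold.p_value, rel_tol):
            return False
    if gold.or_value is not None:
        if pred.or_value is None or not values_close(pred.or_value, gold.or_value, rel_tol):
            return False
    return True


def score(
    predicted: list[AssociationRecord],
    gold: list[GoldAnnotation],
    rel_tol: float = 1e-6,
) -> Metrics:
    """One-to-one greedy matching of predictions to gold annotations."""
    matched: set[int] = set()
    tp = 0
    for g in gold:
        for i, pred in enumerate(predicted):
            if i in matched:
                continue
            if _compatible(pred, g, rel_tol):
                matched.add(i)
                tp += 1
                break
    return Metrics(tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)
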