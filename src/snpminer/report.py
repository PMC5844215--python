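"""Assembly, sorting and tabular serialization of association records.

The flat :class:`AssociationRecord` is the tool's unit of output: one row
per (evidence sentence, rsID) pair, carrying the statistics paired in that
sentence plus the abstract-level cohort fields.  Tables are written as
TSV/CSV with a fixed header, or as JSON with absent keys omitted; floats
render as 6-decimal scientific notation ("3.540000e-18") so files diff
cleanly.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path

from .abstract_io import AbstractRecord
from .associations import AssociationPair
from .cohort import CohortInfo

logger = logging.getLogger(__name__)

TABLE_HEADER = (
    "rsid", "p_comparator", "p_value", "or_value", "patient_size",
    "control_size", "ethnicity", "pmid", "pub_date", "evidence_sentence",
)

SORT_KEYS = (
    "p_value", "or_value", "patient_size", "control_size",
    "pub_date", "pmid", "rsid",
)

_FLOAT_FIELDS = {"p_value", "or_value"}
_INT_FIELDS = {"patient_size", "control_size"}


@dataclass(frozen=True)
class AssociationRecord:
    rsid: str
    pmid: str
    evidence_sentence: str
    p_value: float | None = None
    p_comparator: str | None = None
    or_value: float | None = None
    patient_size: int | None = None
    control_size: int | None = None
    ethnicity: str | None = None
    pub_date: str | None = None

    def __post_init__(self) -> None:
        if not self.rsid or not self.pmid:
            raise ValueError("rsid and pmid are mandatory")
        if not self.evidence_sentence:
            raise ValueError("evidence sentence must be non-empty")


def assemble_records(
    record: AbstractRecord,
    pairs: list[AssociationPair],
    cohort: CohortInfo,
) -> list[AssociationRecord]:
    """One output row per association pair; cohort fields are abstract-level
    and are copied onto every row from that abstract."""
    return [
        AssociationRecord(
            rsid=pair.rsid,
            pmid=record.pmid,
            evidence_sentence=pair.evidence_sentence,
            p_value=pair.p_value.value if pair.p_value else None,
            p_comparator=pair.p_value.comparator if pair.p_value else None,
            or_value=pair.or_value.value if pair.or_value else None,
            patient_size=cohort.patient_size,
            control_size=cohort.control_size,
            ethnicity=cohort.ethnicity,
            pub_date=record.pub_date,
        )
        for pair in pairs
    ]


def _rsid_number(rsid: str) -> int:
    m = re.search(r"\d+", rsid)
    return int(m.group()) if m else 0


def sort_records(
    records: list[AssociationRecord],
    key: str,
    ascending: bool = True,
) -> list[AssociationRecord]:
    """Stable sort; rows missing the key always sort last; rsIDs compare by
    their numeric part."""
    if key not in SORT_KEYS:
        raise ValueError(f"unknown sort key {key!r}; expected one of {SORT_KEYS}")

    def value_of(rec: AssociationRecord):
        v = getattr(rec, key)
        if key == "rsid":
            return _rsid_number(v)
        return v

    present = [r for r in records if value_of(r) is not None]
    missing = [r for r in records if value_of(r) is None]
    present.sort(key=value_of, reverse=not ascending)
    return present + missing


def _cell(field: str, value) -> str:
    if value is None:
        return ""
    if field in _FLOAT_FIELDS:
        return f"{value:.6e}"
    return str(value)


def write_table(
    records: list[AssociationRecord],
    fmt: str,
    destination: str | Path | io.TextIOBase,
) -> None:
    """Serialize records as ``tsv``, ``csv`` or ``json`` to a path or
    text stream."""
    if fmt not in ("tsv", "csv", "json"):
        raise ValueError(f"unknown format {fmt!r}")
    own = isinstance(destination, (str, Path))
    if own:
        try:
            stream = open(destination, "w", encoding="utf-8", newline="")
        except OSError as exc:
            raise OSError(f"cannot write table to {destination}: {exc}") from exc
    else:
        stream = destination
    try:
        if fmt == "json":
            payload = [
                {k: v for k, v in asdict(rec).items() if v is not None}
                for rec in records
            ]
            json.dump(payload, stream, indent=2, ensure_ascii=False)
            stream.write("\n")
        else:
            writer = csv.writer(stream, delimiter="\t" if fmt == "tsv" else ",")
            writer.writerow(TABLE_HEADER)
            for rec in records:
                row = asdict(rec)
                writer.writerow([_cell(f, row[f]) for f in TABLE_HEADER])
    finally:
        if own:
            stream.close()


def read_table(
    source: str | Path | io.TextIOBase,
    fmt: str = "tsv",
) -> list[AssociationRecord]:
    """Inverse of :func:`write_table` for TSV/CSV tables."""
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown table format {fmt!r}")
    own = isinstance(source, (str, Path))
    stream = open(source, encoding="utf-8", newline="") if own else source
    try:
        reader = csv.reader(stream, delimiter="\t" if fmt == "tsv" else ",")
        header = tuple(next(reader))
        if header != TABLE_HEADER:
            raise ValueError(f"unexpected table header: {header}")
        records = []
        for row in reader:
            fields = dict(zip(TABLE_HEADER, row))
            kwargs = {}
            for name, raw in fields.items():
                if raw == "":
                    kwargs[name] = None
                elif name in _FLOAT_FIELDS:
                    kwargs[name] = float(raw)
                elif name in _INT_FIELDS:
                    kwargs[name] = int(raw)
                else:
                    kwargs[name] = raw
            records.append(AssociationRecord(**kwargs))
        return records
    finally:
        if own:
            stream.close()
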