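"""End-to-end orchestration: records in, association rows out."""

from __future__ import annotations

import logging

from .abstract_io import AbstractRecord, filter_records
from .associations import extract_associations
from .cohort import extract_cohort
from .config import Config
from .nlp import analyze
from .report import AssociationRecord, assemble_records
from .snps import find_snp_mentions

logger = logging.getLogger(__name__)


def snp_detector(text: str) -> bool:
    """Predicate used by the relevance filter: any rsID mention present."""
    return bool(find_snp_mentions(text))


def process_record(
    record: AbstractRecord, config: Config | None = None
) -> list[AssociationRecord]:
    """Extract all association rows from one (already filtered) record."""
    config = config or Config()
    parsed = analyze(record.abstract, backend=config.nlp_backend)
    pairs = extract_associations(record.pmid, parsed, config.p_marker_variants)
    cohort = extract_cohort(
        parsed,
        patient_keywords=config.patient_keywords,
        control_keywords=config.control_keywords,
        min_nationality_length=config.min_nationality_length,
    )
    return assemble_records(record, pairs, cohort)


def run_pipeline(
    records: list[AbstractRecord], config: Config | None = None
) -> list[AssociationRecord]:
    """Filter records (keep-first on duplicate PMIDs) and extract from the
    survivors, preserving input order."""
    config = config or Config()
    seen: set[str] = set()
    unique = []
    for rec in records:
        if rec.pmid in seen:
            continue
        seen.add(rec.pmid)
        unique.append(rec)
    rows: list[AssociationRecord] = []
    for outcome in filter_records(unique, snp_detector):
        if not outcome.kept:
            logger.debug("PMID %s dropped: %s", outcome.record.pmid, outcome.reason)
            continue
        rows.extend(process_record(outcome.record, config))
    return rows


def extract_from_text(
    text: str, pmid: str = "0", config: Config | None = None
) -> list[AssociationRecord]:
    """Convenience entry point: run the extractor on one bare abstract or
    sentence (no relevance filtering)."""
    record = AbstractRecord(pmid=pmid, abstract=text)
    return process_record(record, config)
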