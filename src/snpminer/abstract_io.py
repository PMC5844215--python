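"""PubMed query building, record fetching/reading, and relevance filtering.

Live mode builds a disease query constrained to the three MeSH headings
that bracket SNP-association research, fetches PMIDs via NCBI E-utilities
(esearch) and records via efetch.  Offline mode reads PubMed/MEDLINE
``PubmedArticleSet`` XML, or a minimal plain-text dialect (blank-line
separated records; first line ``PMID<TAB>pmid``, optional
``TITLE<TAB>...`` line, remaining lines the abstract).

Records are then filtered to usable, SNP-relevant ones: an abstract must be
present and non-trivial, the record must not be tagged as non-English, and
the title+abstract must mention at least one rsID.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable

from lxml import etree

logger = logging.getLogger(__name__)

ESEARCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"

# an abstract this short is a title-only stub, treated as missing
MIN_ABSTRACT_LENGTH = 50

_MESH_CLAUSES = (
    "Polymorphism, Single Nucleotide",
    "Genetic Predisposition to Disease",
    "Genome-Wide Association Study",
)

_MONTHS = {
    "jan": "01", "feb": "02", "mar": "03", "apr": "04", "may": "05",
    "jun": "06", "jul": "07", "aug": "08", "sep": "09", "oct": "10",
    "nov": "11", "dec": "12",
}

KEPT = "kept"
MISSING_ABSTRACT = "missing_abstract"
NON_ENGLISH = "non_english"
NO_SNP_MENTION = "no_snp_mention"


class FetchError(RuntimeError):
    """Retryable E-utilities failure; carries the transport detail."""


class PubMedXMLError(ValueError):
    """Malformed PubMed XML; message names the position."""


@dataclass(frozen=True)
class AbstractRecord:
    pmid: str
    title: str = ""
    abstract: str = ""
    pub_date: str | None = None     # ISO-ish: YYYY[-MM[-DD]]
    language: str | None = None     # e.g. "eng"

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise ValueError(f"pmid must be a non-empty digit string, got {self.pmid!r}")


@dataclass(frozen=True)
class FilterOutcome:
    record: AbstractRecord
    kept: bool
    reason: str

    def __post_init__(self) -> None:
        if (self.reason == KEPT) != self.kept:
            raise ValueError("reason must be 'kept' exactly when kept is true")


def build_query(disease: str) -> str:
    """PubMed query for SNP-association studies of ``disease``.

    The disease term is AND-ed with the OR of three MeSH headings; the
    output is byte-stable for a given input.
    """
    disease = disease.strip()
    if not disease:
        raise ValueError("disease term must be non-empty")
    mesh = " OR ".join(f'"{clause}"[Mesh Terms]' for clause in _MESH_CLAUSES)
    return f"{disease} AND({mesh})"


def _default_transport(url: str, params: dict) -> bytes:
    from urllib.parse import urlencode
    from urllib.request import urlopen

    try:
        with urlopen(f"{url}?{urlencode(params)}", timeout=60) as resp:
            return resp.read()
    except Exception as exc:  # noqa: BLE001 - wrapped with transport detail
        raise FetchError(f"esearch request failed: {exc}") from exc


def fetch_pmids(
    query: str,
    retmax: int = 3000,
    *,
    email: str | None = None,
    tool: str = "snpminer",
    transport: Callable[[str, dict], bytes] | None = None,
) -> list[str]:
    """esearch PMIDs for ``query``, at most ``retmax``, in service order.

    ``transport`` may be replaced (e.g. by a recorded-response stub in
    tests); the default uses urllib against the NCBI endpoint.  Failures
    raise :class:`FetchError` with the underlying detail.
    """
    if retmax < 1:
        raise ValueError("retmax must be positive")
    params = {"db": "pubmed", "term": query, "retmax": str(retmax), "tool": tool}
    if email:
        params["email"] = email
    logger.info("esearch retmax=%d query=%r", retmax, query)
    payload = (transport or _default_transport)(ESEARCH_URL, params)
    try:
        root = etree.fromstring(payload)
    except etree.XMLSyntaxError as exc:
        raise FetchError(f"esearch returned malformed XML: {exc}") from exc
    ids = [el.text for el in root.findall(".//IdList/Id") if el.text]
    return ids[:retmax]


def _iso_date(pubdate_el: etree._Element | None) -> str | None:
    if pubdate_el is None:
        return None
    year = pubdate_el.findtext("Year")
    if not year:
        return None
    month = (pubdate_el.findtext("Month") or "").strip()
    month = _MONTHS.get(month[:3].lower(), month if month.isdigit() else "")
    day = (pubdate_el.findtext("Day") or "").strip()
    date = year
    if month:
        date += f"-{int(month):02d}"
        if day.isdigit():
            date += f"-{int(day):02d}"
    return date


def read_pubmed_xml(stream: io.IOBase | bytes | str) -> list[AbstractRecord]:
    """Parse a ``PubmedArticleSet`` into records.

    Multi-section abstracts are concatenated with single spaces in document
    order; the citation's language element is kept when present.  Articles
    without a PMID are skipped with a warning; malformed XML raises
    :class:`PubMedXMLError` naming the position.
    """
    if isinstance(stream, str):
        stream = stream.encode()
    if isinstance(stream, bytes):
        stream = io.BytesIO(stream)
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as exc:
        raise PubMedXMLError(f"malformed PubMed XML: {exc}") from exc
    records = []
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//MedlineCitation/PMID")
        if not pmid or not pmid.strip().isdigit():
            logger.warning("article without usable PMID skipped")
            continue
        title = "".join(
            (article.find(".//ArticleTitle").itertext())
            if article.find(".//ArticleTitle") is not None
            else ()
        ).strip()
        sections = [
            " ".join("".join(el.itertext()).split())
            for el in article.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(s for s in sections if s)
        language = article.findtext(".//MedlineCitation/Article/Language")
        pub_date = _iso_date(article.find(".//Article/Journal/JournalIssue/PubDate"))
        records.append(
            AbstractRecord(
                pmid=pmid.strip(),
                title=title,
                abstract=abstract,
                pub_date=pub_date,
                language=language,
            )
        )
    return records


def read_plain_text(stream: io.IOBase | str) -> list[AbstractRecord]:
    """Read the blank-line-separated plain-text record dialect."""
    if hasattr(stream, "read"):
        stream = stream.read()
    if isinstance(stream, bytes):
        stream = stream.decode()
    records = []
    for lineno_block in _blocks(stream):
        start_line, block = lineno_block
        lines = block.splitlines()
        first = lines[0]
        if not first.startswith("PMID\t"):
            raise ValueError(
                f"line {start_line}: record must start with 'PMID<TAB>pmid'"
            )
        pmid = first.split("\t", 1)[1].strip()
        title = ""
        body = lines[1:]
        if body and body[0].startswith("TITLE\t"):
            title = body[0].split("\t", 1)[1].strip()
            body = body[1:]
        records.append(
            AbstractRecord(pmid=pmid, title=title, abstract=" ".join(body).strip())
        )
    return records


def _blocks(text: str) -> Iterable[tuple[int, str]]:
    lineno = 1
    for chunk in re.split(r"\n\s*\n", text):
        stripped = chunk.strip("\n")
        if stripped.strip():
            yield lineno, stripped
        lineno += chunk.count("\n") + 2


def write_plain_text(records: list[AbstractRecord]) -> str:
    """Render records in the plain-text dialect (round-trips with the reader
    for single-paragraph abstracts)."""
    blocks = []
    for rec in records:
        lines = [f"PMID\t{rec.pmid}"]
        if rec.title:
            lines.append(f"TITLE\t{rec.title}")
        if rec.abstract:
            lines.append(rec.abstract)
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def filter_records(
    records: list[AbstractRecord],
    snp_detector: Callable[[str], bool],
) -> list[FilterOutcome]:
    """Apply the usability filters, one outcome per record, order preserved.

    Rules fire in a fixed order: missing/incomplete abstract (empty or
    shorter than 50 characters), non-English language
    tag, then no rsID mention in title+abstract.  Records without a
    language tag are kept at the language step.  Duplicate PMIDs are
    logged; every record still receives an outcome.
    """
    seen: set[str] = set()
    outcomes = []
    for rec in records:
        if rec.pmid in seen:
            logger.info("duplicate PMID %s encountered; keep-first applies", rec.pmid)
        seen.add(rec.pmid)
        if len(rec.abstract.strip()) < MIN_ABSTRACT_LENGTH:
            outcomes.append(FilterOutcome(rec, False, MISSING_ABSTRACT))
        elif rec.language and not rec.language.lower().startswith("en"):
            outcomes.append(FilterOutcome(rec, False, NON_ENGLISH))
        elif not snp_detector(f"{rec.title} {rec.abstract}"):
            outcomes.append(FilterOutcome(rec, False, NO_SNP_MENTION))
        else:
            outcomes.append(FilterOutcome(rec, True, KEPT))
    return outcomes
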