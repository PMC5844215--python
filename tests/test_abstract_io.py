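"""Query building, PubMed XML / plain-text reading, and filtering."""

import pytest

from snpminer import (
    build_query,
    fetch_pmids,
    filter_records,
    read_plain_text,
    read_pubmed_xml,
    snp_detector,
    write_plain_text,
)
from snpminer.abstract_io import AbstractRecord, FetchError, PubMedXMLError

LONG = "x" * 60


def article(pmid, abstract_parts, title="T", language="eng", with_pmid=True):
    pmid_el = f"<PMID>{pmid}</PMID>" if with_pmid else ""
    sections = "".join(
        f'<AbstractText Label="L{i}">{part}</AbstractText>'
        for i, part in enumerate(abstract_parts)
    )
    abstract = f"<Abstract>{sections}</Abstract>" if abstract_parts else ""
    return f"""
      <PubmedArticle><MedlineCitation>{pmid_el}
        <Article>
          <Journal><JournalIssue><PubDate>
            <Year>2015</Year><Month>Jun</Month><Day>4</Day>
          </PubDate></JournalIssue></Journal>
          <ArticleTitle>{title}</ArticleTitle>
          {abstract}
          <Language>{language}</Language>
        </Article>
      </MedlineCitation></PubmedArticle>"""


def article_set(*articles):
    return f"<PubmedArticleSet>{''.join(articles)}</PubmedArticleSet>".encode()


class TestBuildQuery:
    def test_template(self):
        assert build_query("obesity") == (
            'obesity AND("Polymorphism, Single Nucleotide"[Mesh Terms] OR '
            '"Genetic Predisposition to Disease"[Mesh Terms] OR '
            '"Genome-Wide Association Study"[Mesh Terms])'
        )

    def test_multiword_disease_substituted(self):
        q = build_query("lung cancer")
        assert q.startswith("lung cancer AND(")
        assert q.count("[Mesh Terms]") == 3

    @pytest.mark.parametrize("bad", ["", "   ", "\t\n"])
    def test_empty_disease_rejected(self, bad):
        with pytest.raises(ValueError, match="non-empty"):
            build_query(bad)

    def test_byte_stable(self):
        assert build_query("asthma") == build_query(" asthma ")


class TestFetchPmids:
    @staticmethod
    def stub(ids):
        payload = (
            "<eSearchResult><IdList>"
            + "".join(f"<Id>{i}</Id>" for i in ids)
            + "</IdList></eSearchResult>"
        ).encode()
        return lambda url, params: payload

    def test_stub_transport_returns_ids_verbatim(self):
        ids = ["111", "222", "333"]
        assert fetch_pmids("q", transport=self.stub(ids)) == ids

    def test_retmax_bound_respected(self):
        assert fetch_pmids("q", retmax=1, transport=self.stub(["1", "2", "3"])) == ["1"]

    def test_transport_failure_wrapped(self):
        def boom(url, params):
            raise FetchError("HTTP 503 from esearch")

        with pytest.raises(FetchError, match="503"):
            fetch_pmids("q", transport=boom)

    def test_invalid_retmax(self):
        with pytest.raises(ValueError):
            fetch_pmids("q", retmax=0, transport=self.stub([]))


class TestReadPubmedXml:
    def test_two_articles_one_without_abstract(self):
        xml = article_set(
            article("1001", ["first abstract text"]),
            article("1002", []),
        )
        recs = read_pubmed_xml(xml)
        assert [(r.pmid, r.abstract) for r in recs] == [
            ("1001", "first abstract text"),
            ("1002", ""),
        ]
        assert recs[0].language == "eng"
        assert recs[0].pub_date == "2015-06-04"

    def test_labeled_sections_concatenated_in_order(self):
        xml = article_set(article("7", ["Background.", "Methods.", "Results."]))
        (rec,) = read_pubmed_xml(xml)
        assert rec.abstract == "Background. Methods. Results."

    def test_empty_set(self):
        assert read_pubmed_xml(b"<PubmedArticleSet/>") == []

    def test_article_without_pmid_skipped(self):
        xml = article_set(article("", ["abstract"], with_pmid=False), article("9", ["a"]))
        recs = read_pubmed_xml(xml)
        assert [r.pmid for r in recs] == ["9"]

    def test_malformed_xml_names_position(self):
        with pytest.raises(PubMedXMLError, match="line"):
            read_pubmed_xml(b"<PubmedArticleSet><broken")


class TestPlainTextDialect:
    def test_roundtrip_single_paragraph(self):
        recs = [
            AbstractRecord(pmid="12", title="A title", abstract="One paragraph rs123."),
            AbstractRecord(pmid="13", abstract="Another abstract entirely."),
        ]
        again = read_plain_text(write_plain_text(recs))
        assert [(r.pmid, r.title, r.abstract) for r in again] == [
            (r.pmid, r.title, r.abstract) for r in recs
        ]

    def test_bad_header_line(self):
        with pytest.raises(ValueError, match="PMID"):
            read_plain_text("NOPE\t12\nabstract text\n")


class TestFilterRecords:
    def test_reason_precedence_and_order_preserved(self):
        records = [
            AbstractRecord(pmid="1", abstract=""),
            AbstractRecord(pmid="2", abstract=f"rs123 {LONG}", language="fre"),
            AbstractRecord(pmid="3", abstract=f"no snp here {LONG}", language="eng"),
            AbstractRecord(pmid="4", abstract=f"rs7086803 {LONG}", language="eng"),
            AbstractRecord(pmid="5", abstract=f"rs1 {LONG}"),  # no tag: kept
        ]
        outcomes = filter_records(records, snp_detector)
        assert [o.record.pmid for o in outcomes] == ["1", "2", "3", "4", "5"]
        assert [o.reason for o in outcomes] == [
            "missing_abstract", "non_english", "no_snp_mention", "kept", "kept",
        ]
        assert [o.kept for o in outcomes] == [False, False, False, True, True]

    def test_short_abstract_counts_as_missing(self):
        (o,) = filter_records(
            [AbstractRecord(pmid="1", abstract="rs1 tiny")], snp_detector
        )
        assert o.reason == "missing_abstract"

    def test_title_scanned_for_snps(self):
        (o,) = filter_records(
            [AbstractRecord(pmid="1", title="Role of rs123", abstract=LONG)],
            snp_detector,
        )
        assert o.kept

    def test_records_not_mutated_and_counts_match(self):
        records = [AbstractRecord(pmid="1", abstract=LONG)] * 3
        outcomes = filter_records(records, snp_detector)
        assert len(outcomes) == len(records)
        assert all(o.record is r for o, r in zip(outcomes, records))
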