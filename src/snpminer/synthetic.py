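"""Synthetic gold-labelled abstracts for offline testing and calibration.

The generator emulates the micro-structure of GWAS abstracts that the
extractor targets: result sentences in the field's notational dialects
(parenthesized and caret exponents, e-notation, plain decimals), odds
ratios co-reported with P-values, two-SNP "respectively" constructs
optionally guarded by a genome-wide significance threshold, single-value
sentences covering several SNPs, case/control count sentences, nationality
mentions, and distractors (threshold-only statements, bare numbers, gene
symbols).  Every planted association is recorded in a machine-readable
gold list, so pipeline output can be scored against known truth.

With the default (noise-free) parameters every planted association is
expressible within one sentence in marker-bound form, so a correct
extractor recovers the gold exactly.  The one modelled failure mode is the
"P = a and b" construct, where the second value carries no marker: enable
``unmarked_second_value_probability`` to plant associations the extractor
must miss (and mis-broadcast), driving recall and precision below 1 in a
controlled way.

Everything is driven by one seeded RNG: a fixed (n, seed, params) triple
reproduces the corpus byte for byte.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .abstract_io import AbstractRecord, write_plain_text
from .associations import parse_number
from .evaluation import GoldAnnotation, write_gold_tsv

MINUS = "−"  # typographic minus, as typeset in journals

_DISEASES = (
    "obesity", "asthma", "narcolepsy", "COPD", "schizophrenia",
    "lung cancer", "breast cancer", "ischemic stroke", "metabolic syndrome",
)
_GENES = (
    "TP63", "CHEK2", "BRCA2", "IREB2", "NRXN3", "CPT1B", "IL1B", "APOA5",
    "TERT", "CTSS", "FTO", "TCF7L2", "CDKN2A", "MC4R",
)
_CYTOBANDS = (
    "10q25.2", "6q22.2", "6p21.32", "3q28", "5p15.33", "13q12.12", "22q12.2",
    "15q25.1", "9p21.3",
)
_NATIONALITIES = (
    "Finnish", "Chinese", "Japanese", "Turkish", "Korean", "German",
    "Italian", "Mexican", "Egyptian", "Icelandic",
)
_PLATFORMS = ("SNPscan", "Illumina", "Affymetrix", "TaqMan")


@dataclass(frozen=True)
class SyntheticParams:
    """Composition and noise settings, all probabilities in [0, 1]."""

    result_sentences: tuple[int, int] = (1, 2)
    or_probability: float = 0.4
    multi_probability: float = 0.35
    broadcast_probability: float = 0.2
    threshold_probability: float = 0.4
    cohort_probability: float = 0.9
    ethnicity_probability: float = 0.6
    filler_sentences: tuple[int, int] = (1, 3)
    unmarked_second_value_probability: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "or_probability", "multi_probability", "broadcast_probability",
            "threshold_probability", "cohort_probability",
            "ethnicity_probability", "unmarked_second_value_probability",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("result_sentences", "filler_sentences"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-decreasing pair, got {(lo, hi)}")
        if self.result_sentences[0] < 1:
            raise ValueError("each abstract needs at least one result sentence")


@dataclass(frozen=True)
class SyntheticCorpus:
    records: tuple[AbstractRecord, ...]
    gold: tuple[GoldAnnotation, ...]
    # counts of deliberately planted failure modes, for test bookkeeping
    planted_unmarked: int

    @property
    def abstracts_text(self) -> str:
        return write_plain_text(list(self.records))

    @property
    def gold_tsv(self) -> str:
        return write_gold_tsv(list(self.gold))


def _sample_rsid(rng: random.Random, used: set[str]) -> str:
    while True:
        digits = rng.randint(1, 8)
        lo = 10 ** (digits - 1) if digits > 1 else 1
        rsid = f"rs{rng.randrange(lo, 10 ** digits)}"
        if rsid not in used:
            used.add(rsid)
            return rsid


def _render_p(rng: random.Random) -> tuple[str, float]:
    """A P-value log-uniform in [1e-30, 0.05], rendered in a random dialect.

    The gold value is obtained by re-parsing the rendered string, so gold
    and extractor agree to the last bit.
    """
    u = rng.uniform(math.log10(1e-30), math.log10(0.05))
    k = math.floor(u)
    mantissa = round(10 ** (u - k), 2)
    if mantissa >= 10.0:
        mantissa, k = 1.0, k + 1
    m = f"{mantissa:g}"
    dialects = ["paren", "caret", "enote"]
    if k >= -4:
        dialects.append("plain")
    dialect = rng.choice(dialects)
    if dialect == "paren":
        text = f"{m} × 10({MINUS}{abs(k)})"
    elif dialect == "caret":
        text = f"{m} ×10^{MINUS}{abs(k)}"
    elif dialect == "enote":
        text = f"{m}e-{abs(k)}"
    else:
        text = "0." + "0" * (abs(k) - 1) + m.replace(".", "")
    return text, parse_number(text)


def _render_or(rng: random.Random) -> tuple[str, float]:
    text = f"{rng.uniform(0.2, 3.5):.2f}"
    return text, float(text)


@dataclass
class _ResultSentence:
    text: str
    planted: list[tuple[str, float | None, float | None]]  # rsid, p, or
    unmarked: int = 0


def _make_result_sentence(
    rng: random.Random, used_rsids: set[str], params: SyntheticParams
) -> _ResultSentence:
    disease = rng.choice(_DISEASES)
    gene = rng.choice(_GENES)
    cyto = rng.choice(_CYTOBANDS)
    r = rng.random()
    if r < params.unmarked_second_value_probability:
        rs1, rs2 = _sample_rsid(rng, used_rsids), _sample_rsid(rng, used_rsids)
        (p1_txt, p1), (p2_txt, p2) = _render_p(rng), _render_p(rng)
        return _ResultSentence(
            text=(
                f"Two SNPs {rs1} and {rs2} in {gene} were associated with "
                f"{disease} (P = {p1_txt} and {p2_txt})."
            ),
            planted=[(rs1, p1, None), (rs2, p2, None)],
            unmarked=1,
        )
    r -= params.unmarked_second_value_probability
    if r < params.multi_probability:
        rs1, rs2 = _sample_rsid(rng, used_rsids), _sample_rsid(rng, used_rsids)
        (p1_txt, p1), (p2_txt, p2) = _render_p(rng), _render_p(rng)
        prefix = (
            f"Associations reaching genome-wide significance "
            f"(P ≤ 5.0 × 10({MINUS}8)) were identified in "
            if rng.random() < params.threshold_probability
            else "Genome-wide significant associations were observed in "
        )
        return _ResultSentence(
            text=(
                f"{prefix}{gene} ({rs1} and {rs2} at {cyto}, "
                f"P = {p1_txt} and P = {p2_txt}, respectively)."
            ),
            planted=[(rs1, p1, None), (rs2, p2, None)],
        )
    r -= params.multi_probability
    if r < params.broadcast_probability:
        rs1, rs2 = _sample_rsid(rng, used_rsids), _sample_rsid(rng, used_rsids)
        p_txt, p = _render_p(rng)
        return _ResultSentence(
            text=(
                f"Both {rs1} and {rs2} showed significant association with "
                f"{disease} (P = {p_txt})."
            ),
            planted=[(rs1, p, None), (rs2, p, None)],
        )
    rsid = _sample_rsid(rng, used_rsids)
    p_txt, p = _render_p(rng)
    if rng.random() < params.or_probability:
        or_txt, or_val = _render_or(rng)
        return _ResultSentence(
            text=(
                f"We identified a susceptibility locus for {disease} at "
                f"{cyto} ({rsid}, OR = {or_txt}, P = {p_txt})."
            ),
            planted=[(rsid, p, or_val)],
        )
    return _ResultSentence(
        text=f"We identified a susceptibility locus at {cyto} ({rsid}, P = {p_txt}).",
        planted=[(rsid, p, None)],
    )


def _filler_sentence(rng: random.Random) -> str:
    kind = rng.randrange(4)
    if kind == 0:
        return f"The mean age of participants was {rng.uniform(30, 75):.1f} years."
    if kind == 1:
        g1, g2 = rng.sample(_GENES, 2)
        return (
            f"Variants in {g1} and {g2} were genotyped using the "
            f"{rng.choice(_PLATFORMS)} platform."
        )
    if kind == 2:
        return f"Genome-wide significance was defined as P ≤ 5.0 × 10({MINUS}8)."
    return "Replication was performed in an independent validation cohort."


def generate_synthetic_abstracts(
    n: int,
    seed: int,
    params: SyntheticParams | None = None,
) -> SyntheticCorpus:
    """Generate ``n`` gold-labelled abstracts, deterministically from
    ``(n, seed, params)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or SyntheticParams()
    rng = random.Random(seed)
    records: list[AbstractRecord] = []
    gold: list[GoldAnnotation] = []
    planted_unmarked = 0
    for i in range(n):
        pmid = str(90000000 + i)
        used_rsids: set[str] = set()
        disease = rng.choice(_DISEASES)
        sentences: list[_ResultSentence | str] = []
        if rng.random() < params.ethnicity_probability:
            nat = rng.choice(_NATIONALITIES)
            sentences.append(
                f"We investigated genetic susceptibility to {disease} in a "
                f"{nat} population."
            )
        if rng.random() < params.cohort_probability:
            n_cases = rng.randint(100, 5000)
            n_controls = rng.randint(100, 9000)
            sep = rng.random() < 0.3  # sometimes thousands-grouped
            sentences.append(
                f"We conducted a case-control study of "
                f"{n_cases:,} {disease} cases and "
                f"{n_controls:,} healthy controls."
                if sep
                else f"We conducted a case-control study of "
                f"{n_cases} {disease} cases and {n_controls} healthy controls."
            )
        n_results = rng.randint(*params.result_sentences)
        for _ in range(n_results):
            rs = _make_result_sentence(rng, used_rsids, params)
            sentences.append(rs)
            planted_unmarked += rs.unmarked
        for _ in range(rng.randint(*params.filler_sentences)):
            sentences.append(_filler_sentence(rng))
        rng.shuffle(sentences)
        texts = []
        for sent_id, sent in enumerate(sentences):
            if isinstance(sent, _ResultSentence):
                texts.append(sent.text)
                for rsid, p, or_val in sent.planted:
                    gold.append(
                        GoldAnnotation(
                            pmid=pmid,
                            rsid=rsid,
                            p_value=p,
                            or_value=or_val,
                            sentence_id=sent_id,
                        )
                    )
            else:
                texts.append(sent)
        records.append(
            AbstractRecord(
                pmid=pmid,
                title=f"Genetic association study of {disease}.",
                abstract=" ".join(texts),
            )
        )
    return SyntheticCorpus(
        records=tuple(records),
        gold=tuple(gold),
        planted_unmarked=planted_unmarked,
    )
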