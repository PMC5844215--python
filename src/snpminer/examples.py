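"""Curated evidence sentences from published GWAS abstracts.

Each entry is a single sentence as printed in the abstract of the PubMed
record named by the key, chosen to cover the notational dialects the
extractor must handle: caret and parenthesized exponents, combined-analysis
P markers, odds ratios co-reported with P-values, multi-SNP
"respectively" constructs guarded by a genome-wide significance threshold,
duplicate rsID mentions, marker-less second values, case/control counts and
nationality mentions.  They drive the worked examples in the README, the
regression tests, and the acceptance script.

Keys are PubMed IDs; the one abstract contributing two sentences is
suffixed ``a``/``b``.
"""

from __future__ import annotations

EXAMPLE_SENTENCES: dict[str, str] = {
    "21552555": (
        "We next examined obesity-related quantitative traits such as total "
        "body weight, waist circumference and waist to hip ratio, and "
        "detected genome-wide significant signals between waist to hip ratio "
        "and NRXN3 rs11624704, P = 2.67 ×10−9, previously associated with "
        "body weight and fat distribution."
    ),
    "23143601": (
        "We identified three new susceptibility loci at 10q25.2 (rs7086803, "
        "P = 3.54 × 10(−18)), 6q22.2 (rs9387478, P = 4.14 × 10(−10)) and "
        "6p21.32 (rs2395185, P = 9.51 × 10(−9))."
    ),
    "24880342": (
        "We identified large-effect GWASs for squamous lung cancer with the "
        "rare variants BRCA2 p.Lys3326X (rs11571833, OR = 2.47, "
        "P = 4.74 × 10(−20)) and CHEK2 p.Ile157Thr (rs17879961, OR = 0.38, "
        "P = 1.27 × 10(−13))."
    ),
    "21725308": (
        "The combined analyses identified six well-replicated SNPs with "
        "independent effects and significant lung cancer associations "
        "(P ≤ 5.0 × 10(−8)) located in TP63 (rs4488809 at 3q28, "
        "P = 7.2 × 10(−26)), TERT-CLPTM1L (rs465498 and rs2736100 at "
        "5p15.33, P = 1.2 × 10(−20) and P = 1.0 × 10(−27), respectively), "
        "MIPEP-TNFRSF19 (rs753955 at 13q12.12, P = 1.5 × 10(−12)) and "
        "MTMR3-HORMAD2-LIF (rs17728461 and rs36600 at 22q12.2, "
        "P = 1.1 × 10(−11) and P = 6.2 × 10(−13), respectively)."
    ),
    "26141218": (
        "We genotyped IL1B SNPs in a case-control study with 889 lung "
        "cancer cases and 1005 controls using the SNPscan Genotyping system."
    ),
    "25245582": (
        "A total of 169 ED patients (106 with anorexia nervosa (AN) and 63 "
        "with bulimia nervosa (BN)) and 312 healthy subjects were genotyped."
    ),
    "22399527a": (
        "We conducted a GWA study on MetS and its component traits in 4 "
        "Finnish cohorts consisting of 2637 MetS cases and 7927 controls."
    ),
    "22399527b": (
        "Therefore, we explored the association between the polymorphisms "
        "of CTSS and metabolic disorders in a Chinese Han population."
    ),
    "22914670": (
        "Two SNPs rs2656069 and rs10851906 in IREB2 were associated with "
        "COPD P = 0.045 and 0.032"
    ),
    "18820697": (
        "rs5770917, a SNP located between CPT1B and CHKB, was associated "
        "with narcolepsy in Japanese (rs5770917[C], OR = 1.79, combined "
        "P = 4.4 × 10(−7)) and other ancestry groups (OR = 1.40, P = 0.02)."
    ),
    "17383819": (
        "Significant association was detected at rs2254298 (P = 0.03) but "
        "not rs53576."
    ),
}


def example_sentence(key: str) -> str:
    """Look up a curated sentence by PubMed ID (plus ``a``/``b`` suffix)."""
    return EXAMPLE_SENTENCES[key]
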