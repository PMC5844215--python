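# snpminer

Text mining of SNP–disease associations from PubMed abstracts.

Genome-wide association studies (GWAS) report their findings in a compact,
highly conventionalized prose: a dbSNP identifier (`rs…`), the statistical
significance of the association (a P-value, often at the genome-wide
threshold P ≤ 5×10⁻⁸), an effect size (odds ratio, OR), and a description
of the cohort — how many cases, how many controls, and from which
population. Manually curated databases such as the GWAS Catalog lag behind
the publication rate, and much of this information never leaves the
abstract text. `snpminer` is for geneticists and curators who want a fast,
reproducible first pass over the literature: query a disease, get back a
sortable table of `(rsID, P, OR, cohort)` records with the evidence
sentence attached.

## What the extractor does

1. **Collect** — builds the PubMed query
   `{disease} AND("Polymorphism, Single Nucleotide"[Mesh Terms] OR
   "Genetic Predisposition to Disease"[Mesh Terms] OR "Genome-Wide
   Association Study"[Mesh Terms])`, fetches up to 3000 records via NCBI
   E-utilities (or reads PubMed XML / plain-text files offline), and keeps
   records that have a usable English abstract mentioning at least one rsID.
2. **Recognize** — finds rsID mentions with a case-insensitive
   `rs\s?[0-9]+` pattern extended to capture a trailing allele letter
   (G/C/T/A), so `rs7086803C` normalizes to `rs7086803` with allele `C`.
3. **Parse statistics** — flags *result sentences* (a P marker bound to a
   number), normalizes the notational dialects
   (`3.54 × 10(−18)`, `2.67 ×10^−9`, `4.74e-20`, `0.045`; markers
   `P-value`, `combined P`, `Pmeta`, …) and parses each marker-bound
   number into a `(kind, comparator, value)` triple. Threshold statements
   (`P ≤ 5.0 × 10(−8)`) are recognized but never paired.
4. **Pair** — within each sentence: if exactly one pairable value of a
   kind exists it is *broadcast* to every SNP; otherwise SNPs consume
   their nearest unconsumed value left-to-right (character distance,
   duplicate mentions deduplicated first). P and OR pairing run
   independently.
5. **Cohort** — numeric-modifier dependencies yield integer candidates
   matched against patient keywords (`patient`, `case`, `subject`) and
   control keywords (`control`, `normal`, `healthy`); the most frequent
   nationality entity of length ≥ 4 becomes the cohort ethnicity.
6. **Report** — one row per (sentence, rsID), sortable by P, OR, group
   sizes, date, PMID or rsID, written as TSV/CSV/JSON.

An evaluation layer scores predicted associations against gold
annotations (precision / recall / F1 with one-to-one matching and value
agreement), and a seeded synthetic-corpus generator plants known
associations in realistic abstract prose so the whole pipeline can be
validated offline against ground truth.

## Worked example

```sh
snpminer extract --pmid 24880342 --text "We identified large-effect GWASs \
for squamous lung cancer with the rare variants BRCA2 p.Lys3326X \
(rs11571833, OR = 2.47, P = 4.74 × 10(−20)) and CHEK2 p.Ile157Thr \
(rs17879961, OR = 0.38, P = 1.27 × 10(−13))."
```

prints (evidence column elided):

```
rsid        p_comparator  p_value       or_value      ...  pmid
rs11571833  =             4.740000e-20  2.470000e+00  ...  24880342
rs17879961  =             1.270000e-13  3.800000e-01  ...  24880342
```

Both variants are correctly coupled to *their own* statistics: the two
P-values and two odds ratios are consumed nearest-first, so `rs11571833`
gets (OR 2.47, P 4.74×10⁻²⁰) and `rs17879961` gets (OR 0.38,
P 1.27×10⁻¹³) — the protective CHEK2 variant is not confused with the
risk-increasing BRCA2 one. The same mechanics handle six-SNP
"respectively" sentences, duplicate mentions, and single-value broadcast
(`rs2254298 (P = 0.03) but not rs53576` assigns 0.03 to both, a known and
deliberate over-assignment).

Other entry points:

```sh
snpminer mine --disease "lung cancer" --offline --input abstracts.xml \
    --sort-key p_value -o results.tsv
snpminer synth --n 50 --seed 1 --out-abstracts corpus.txt --out-gold gold.tsv
snpminer eval --pred results.tsv --gold gold.tsv
```

Python API: `snpminer.extract_from_text(...)`, `run_pipeline(...)`,
`generate_synthetic_abstracts(...)`, `score(...)` — see the module
docstrings.

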