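# Methods

## Problem and scope

`snpminer` extracts SNP–disease association records from PubMed abstracts:
for each reported association, the rsID, the P-value and (when present)
the odds ratio it is coupled to, plus abstract-level cohort descriptors
(patient-group size, control-group size, ethnicity) and the evidence
sentence. Extraction is strictly within-sentence: an association whose SNP
and statistic appear in different sentences is out of reach by design, a
trade-off that keeps the pairing rules transparent and auditable. Only
abstracts and titles are analyzed, never full text.

## Record collection and filtering

The disease query fixes three MeSH headings (single-nucleotide
polymorphism, genetic predisposition to disease, genome-wide association
study) OR-ed together and AND-ed with the user's disease term; up to 3000
PMIDs are taken per query (esearch order preserved, no re-sorting).
Records are excluded, in this order, when (a) the abstract is absent or
shorter than 50 characters — the cut-off that separates title-only stubs
from real abstracts; (b) the citation carries a non-English language tag
(records without a tag are kept: metadata-level filtering only, since a
false exclusion costs an abstract while a false inclusion merely yields
no matches); (c) neither title nor abstract contains an rsID. Duplicate
PMIDs keep the first occurrence.

## rsID recognition

The pattern is case-insensitive `rs`, at most one space, one or more
digits. One space (not arbitrary whitespace) reflects how the split form
actually appears in print. A single trailing G/C/T/A glued to the digits
and followed by a non-alphanumeric boundary is captured as the allele and
stripped from the normalized id; the boundary requirement stops the rule
from chewing into gene symbols, and because the allele must be a letter a
trailing digit can never be stolen from the id. Bracketed alleles
(`rs5770917[C]`) are left outside the mention. Submitted-SNP `ss` ids and
protein-level variant nomenclature (`p.Lys3326X`) are deliberately not
recognized. Within a sentence, repeated mentions of one rsID are merged
into a group that keeps every span.

## Statistic normalization and parsing

Normalization is staged, with a per-character offset map back to the
original sentence maintained across every edit:

1. exponent dialects → e-notation, **before** bracket stripping (the
   parentheses in `3.54 × 10(−18)` are part of the number): mantissa,
   `×`/`x`/`*`, `10`, then a caret, parenthesized, or bare-signed
   exponent; U+2212 minus, en-dash and hyphen-minus all count as signs;
2. typographic minus inside existing e-notation → `-`;
3. quotes and brackets removed;
4. P-marker variants (`P-value`, `P value`, `combined P`, `Pmeta`,
   `P-trend`, … — a config-extensible lexicon) and the bare lowercase `p`
   token → canonical `P`.

A *result sentence* is one whose normalized text binds the canonical P
marker to a parseable number. The number grammar requires a decimal point
or an exponent, so integer counts, years and thousands-grouped numbers
are never statistic values. Comparators `=`, `<`, `≤`, `>`, `≥` are
recognized (plus `of`/`was`/`is` as verbal equality); values written with
`≤` are always thresholds, and `<` counts as a threshold only when an
`=`-comparator value of the same kind coexists in the sentence —
a lone `P < 0.001` is a reported value, but `P < 0.05` next to exact
values is a significance criterion. Thresholds are logged and excluded
from pairing. P-values parsing above 1 are kept but logged, since
malformed texts exist. Range-valued statistics (`P = 0.01–0.04`) are not
modeled; the first bound parses and the rest is ignored.

## Pairing model

Within one sentence, for one statistic kind:

* **Broadcast:** exactly one pairable value → every SNP group receives
  it. This reproduces the reporting style "significant at rs2254298
  (P = 0.03) but not rs53576" at the cost of deliberate false positives —
  the procedure has no negation model, and the same mechanism is what
  turns a missed second value ("P = 0.045 and 0.032") into one wrong
  assignment rather than one missing one.
* **Nearest-unconsumed:** otherwise, SNP groups iterate in
  first-occurrence order; each takes the remaining value minimizing
  character distance between nearest span edges (minimum over the group's
  mention spans), and consumes it. Ties prefer the value *following* the
  SNP, matching the dominant `rsID, P = …` order. Character rather than
  token distance keeps the measure identical across NLP backends.

P-value and odds-ratio pairing run the same procedure over separate
consumption pools ("OR" / "ORs" / "odds ratio" markers; the lowercase
conjunction "or" never matches). Outside broadcast the pairing is
injective, and its output is invariant to the input order of the values.

## Cohort extraction

Integer-valued numeric-modifier dependents become candidates carrying
their head token and a two-token window on each side of the number
(thousands separators accepted, decimals rejected). A candidate is a
patient (control) hit when its head, else any window token, matches the
patient (control) keyword set, case- and plural-insensitively; when both
sets hit one candidate the control reading wins ("312 healthy subjects").
The first hit per set in abstract order is reported, which prefers stated
totals over the parenthesized subgroup breakdowns that follow them.
Subgroup arithmetic is not attempted.

Ethnicity: nationality-category entity spans with at least 4 characters
are counted across the abstract and the most frequent label is reported,
ties to the earliest first occurrence. The 4-character floor removes
acronym noise while keeping short demonyms ("Thai"); it, the keyword
sets, and the marker lexicon are all configurable.

## Linguistic backends

The pipeline consumes a minimal contract — sentences, tokens,
dependency arcs, entity spans, all with offsets into the original
abstract — rather than a specific parser. The default **heuristic**
backend implements it deterministically: rule-based sentence splitting
(terminal punctuation + whitespace + capitalized opener, which decimal
points cannot trigger), a regex tokenizer, numeric-modifier arcs by
attaching each integer to the terminal of the following content-word run
(at most 4 tokens, stopping at closed-class words — so "889 lung cancer
cases" heads at "cases"), with a two-token left fallback ("controls
(n = 1005)"), and lexicon-based nationality tagging over ~150 demonyms
and population labels, requiring capitalization. A **rule_fallback**
backend provides sentences and tokens only; the regex stages behave
identically under it, and cohort matching degrades to the window rule —
adjacent keywords still resolve, but compound nominals put the keyword
three tokens from the number and are then missed (tested and documented,
not hidden). Determinism end to end: repeated runs on the same text give
identical output.

## Synthetic corpus

The generator emulates the micro-structure the extractor targets —
result sentences across all four number dialects, OR co-reporting,
two-SNP "respectively" constructs optionally guarded by an inline
`P ≤ 5.0 × 10(−8)` threshold, single-value multi-SNP sentences,
case/control count sentences (sometimes thousands-grouped), nationality
mentions, and distractors (threshold-only statements, bare decimals, gene
symbols). P-values are sampled log-uniformly on [10⁻³⁰, 0.05] — spanning
genome-wide hits to marginal significance — and odds ratios uniformly on
[0.2, 3.5]; gold values are obtained by re-parsing the rendered string,
so gold and extractor agree to the last bit. Everything derives from one
seeded RNG; a fixed (n, seed, params) triple is byte-reproducible. The
default parameters are noise-free: every planted association is
single-sentence and marker-bound, so a correct pipeline recovers the gold
exactly — which is what the recovery tests assert over seeds 1–20 with 50
abstracts each. The one modeled noise mode plants the "P = a and b"
construct whose unmarked second value the extractor must miss (one false
negative and one broadcast false positive per instance). What the corpus
does **not** emulate: cross-sentence associations, negation and
hedging, range-valued statistics, non-standard variant nomenclature, and
OCR-grade typography — passing on synthetic data therefore bounds
grammar/pairing correctness, not real-corpus recall.

## Evaluation

A prediction matches a gold annotation when PMID and rsID agree and every
value the gold record states is present within relative tolerance 1e-6
(covering float-formatting differences; configurable). Matching is
one-to-one and greedy over gold in order. Value agreement is required —
a SNP coupled to the wrong number is an error, not a hit — so mis-pairing
depresses both precision and recall. Precision, recall and F1 use the
0-when-undefined convention.

## Numerical and formatting choices

Character offsets are 0-based half-open code-point offsets. Table floats
render as `%.6e` (`3.540000e-18`), round-tripping to well under the
scoring tolerance; absent fields are empty cells in TSV/CSV and omitted
keys in JSON. Sorting is stable, missing keys last in either direction,
rsIDs ordered by their numeric part. Test problem sizes (1000 random
pairing instances, 20×50 synthetic abstracts, 300 planted rsIDs) were
chosen to exercise every branch of the pairing and grammar logic while
keeping the full suite comfortably under a couple of minutes.

## Known limitations

* No cross-sentence or coreference reasoning; no negation model (the
  broadcast rule knowingly over-assigns).
* The heuristic numeric-modifier approximation is not a parse; garden-path
  noun phrases can mislead it, and the fallback backend misses
  compound-nominal cohort phrases entirely.
* Nationality tagging is lexicon-bound: labels outside the shipped list
  (or lowercase in the text) are invisible.
* Gold matching ignores sentence ids; an association predicted from the
  wrong sentence with the right values still counts.
* Live-mode behavior depends on the current state of PubMed and is not
  covered by the offline test suite beyond a stubbed transport.
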