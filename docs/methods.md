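# Methods

`slimscreen` implements an in silico screen for candidate protein–protein
interactors based on short linear motifs (SLiMs): a library of tripeptide
probes — peptides experimentally shown to bind a bait protein in vitro —
is matched exactly against every protein of a proteome, and matched
proteins ("P-proteins") are filtered and prioritized by occurrence
statistics, cancer-hallmark pathway membership, domain localization and
somatic-variant overlap.

## Scanning model

Matching is exact over the 20 standard amino-acid letters; ambiguity and
rare-translation codes (X, B, Z, U, O, J) are accepted in sequences but
can never match a probe. Every occurrence is reported: multiple
occurrences of the same probe, overlapping occurrences of different
probes, and self-overlapping occurrences. All coordinates are 1-based
inclusive; a tripeptide at start *s* spans [*s*, *s*+2]. Two counters are
kept strictly separate, because the screening literature uses both: the
**total occurrence count** (the quantitative "at least *k* matches"
filter) and the **distinct-probe count** (the qualitative "at least *k*
different tripeptides" filter, the funnel's headline stage, default
*k* = 4).

"Frequency of occurrence" of a probe has no canonical denominator for
overlapping windows; the package exports raw totals together with the
per-window frequency, total occurrences divided by the number of
scannable windows Σ(L − 2) over proteins with L ≥ 3.

## Null models

Whether probe occurrences are stochastically distributed is judged
against two constructions, reported side by side because the question is
under-determined:

* **Analytic composition model.** The per-window match probability is
  q = Σ_probes Π_residues f(aa) under a background of i.i.d. residues
  (estimated from the proteome, uniform, or user-supplied). Probe
  peptides are unique, so q is exact per window; the per-protein
  probability of ≥1 match is approximated as 1 − (1 − q)^(L−2), treating
  windows as independent. The error of this approximation is second
  order: overlapping windows are dependent, and probe pairs that chain
  (the last two residues of one equal the first two of another) make
  matches cluster. For realistic q (~10⁻³) the error is a fraction of a
  percent of the ≥1-match probability; the test suite quantifies it
  against an exact automaton computation and bounds it a priori by
  (L−2)·(Σ chaining co-occurrence probabilities + 2q²). At q as large as
  0.25 (2-letter-alphabet stress case, enumerated exhaustively) the
  discrepancy reaches ~0.08.
* **Shuffle Monte-Carlo null.** Each replicate independently permutes
  every protein's residues, preserving composition and length exactly,
  and recomputes the P-protein fraction. All stochastic operations take
  an explicit seed that is recorded in outputs.

The observed P-protein count is tested against the expected fraction
with an exact binomial test; two-sided p-values use the tail-doubling
convention min(1, 2·min(P(X ≤ k), P(X ≥ k))), with a one-sided "lower"
alternative selectable and a normal-approximation z-score reported
alongside. Degenerate expectations (0 or 1) are valid only for exactly
matching observations.

**Codon degeneracy.** Each probe is weighted by the number of sense
codons encoding its residues (standard genetic code, 61 sense codons,
derived from Biopython's codon table). Both the sum (range 3–18) and the
product (range 1–216) are computed, since "total number of codons" of a
tripeptide is ambiguous between the two, and each is rank-correlated
(Spearman, mid-ranks for ties) with observed probe frequency. With fewer
than 3 probes the correlation is refused; with zero variance it is
undefined and returned as NaN.

## Enrichment

Pathway gene sets (GMT) roll up into hallmark clusters as deduplicated
unions; a protein counts toward every hallmark it belongs to. Members
may be accessions or gene symbols — resolution tries accession first,
then symbol. Per hallmark the package reports cluster size, P-protein
count, percentage, a one-sided upper-tail hypergeometric p-value against
the screened background, and Benjamini–Hochberg q-values across the
hallmark rows. Rows at or above 45% are flagged as "highest-percentage"
clusters. Percentages are rounded half-up to one decimal on exact
rationals (and rendered with two decimals in reports); this convention
reproduces published-style cells such as 872/2249 → 38.8.

## Funnel and prioritization

The funnel reports, with one-decimal percentages: proteome size →
P-proteins (≥1 occurrence) → hallmark-associated P-proteins → proteins
with ≥k distinct probes → the protein-level intersection of the last
two. An empty proteome is flagged degenerate with all percentages 0.

Domain overlap labels each match *inside* (span fully within a domain),
*partial* (span crosses a boundary; inside takes precedence when several
domains apply) or *outside*. Variant overlap reports every (variant,
match) pair with the variant position inside the match span, with the
within-motif offset 0–2; truncating variants are treated as point
positions at their stated residue.

Candidate ranking is a deterministic, documented stand-in for manual
relevance judgement: keep proteins with ≥k distinct probes or hallmark
members with ≥1 domain-localized match, order descending by (number of
hallmarks, distinct probes, domain hits, variant hits), ties broken by
accession. Re-running is byte-identical.

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes, so every stage is testable without downloads:

* **Proteome.** i.i.d. residues from a configurable background; default
  length distribution log-normal with median 375 and σ = 0.6, resembling
  human protein lengths; a fixed-length mode supports analytic checks; a
  codon-usage preset (f ∝ sense-codon count) supports the
  frequency-vs-degeneracy monotonicity check.
* **Planted motifs** overwrite (never insert) 3-residue windows, keeping
  lengths stable; overlapping plants and out-of-range positions are
  rejected, and the ground-truth match list is returned.
* **Gene sets** sample members without replacement with sampling weight
  equal to the enrichment factor for P-proteins (0 excludes them, 1 is
  uniform); sets group into hallmarks.
* **Variants** place a stated fraction uniformly on (match, offset)
  pairs and the rest uniformly outside all match spans, returning
  ground-truth labels.

All generators are bit-reproducible given (config, seed). What the
synthetic data does **not** emulate: real domain architecture (domains
are arbitrary intervals), residue autocorrelation and low-complexity
regions, isoform redundancy, and database annotation biases — so passing
tests demonstrate correctness of the computation, not biological claims
about any particular proteome.

The packaged default probe library is a synthetic stand-in: only two of
the original nineteen probe sequences are public (LFF, NFW) plus the
first residues of three more; the remainder are constructed rare-residue
tripeptides. Screens of real proteomes should supply the real library as
input.

## Problem sizes used in the shipped checks

Scanner oracle equivalence uses 1,000 random sequence/library pairs
(lengths 0–200, alphabets of size 4 and 20). Null-model consistency uses
one proteome of 20,000 proteins at L = 500 with 1 and 19 probes;
p-value calibration uses 500 replicates of 5,000 proteins at L = 250
with a 5-probe sub-library — sized so that binomial discreteness of the
exact tail-doubled p-values stays small relative to the KS α = 0.01
critical band, and chosen from the first five default probes, which have
no chaining overlaps. Planted-motif recovery uses 100 plants across
1,000 proteins plus 100 in-motif variants; enrichment power uses 100
replicates at set size 200, background 2,000 (20% P-proteins),
enrichment factor 5. The full default run of tests plus the acceptance
script completes in well under a minute on one CPU.

## Known limitations

* The analytic null is first-order; for probe libraries with heavy
  chaining or very long proteins the shuffle Monte-Carlo null is the
  more faithful reference.
* Exact matching only: no PSSM scoring, fuzzy matching, or residue
  similarity classes.
* Enrichment is overlap-based (hypergeometric) over unions of gene
  sets; no ranked-list (GSEA-style) statistics and no pathway topology.
* Gene-set members unresolvable against the proteome are silently
  dropped from cluster counts.
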