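# Methods

This note documents the models, conventions and numerical choices behind
`mitocub`, and what the synthetic-data validation does and does not
establish.

## Ingestion and normalization

Mitochondrial CDS annotations frequently end in incomplete stop codons
(`T` or `TA`, completed by polyadenylation), and a few genes start with
non-ATG codons. Ingestion therefore normalizes every sequence before any
statistic is computed: uppercase, U→T, reject ambiguity codes, drop a
trailing partial codon (with a warning), then drop a terminal complete stop
codon. The result is a stop-free in-frame codon string; an internal stop
after trimming is a validation error reporting the 1-based codon position.
Non-ATG start codons are counted as ordinary codons. Statistics are
computed on the annotated sense strand exactly as extracted — no strand
correction — so minus-strand-encoded genes (ND1, ND4, ND4L, ND5 in insect
mitogenomes) show mirrored PR2 biases, which is informative rather than an
artifact. Genetic codes come from Biopython's NCBI registry; the
synonymous-family structure (e.g. table 5's 8-fold Ser, 6-fold Leu, six
4-fold and twelve 2-fold families) is derived from the codon→amino-acid
map at run time, never hard-coded.

Internal coordinates are 0-based half-open; reported positions 1-based.
FASTA headers use a configurable `species|gene` dialect.

## Composition and aggregation

Percentages are carried at full precision and rounded only in presentation
copies (default 2 decimals). Group summaries are unweighted arithmetic
means over CDS rather than length-weighted pools: the typical use is a
per-gene mean across a handful of near-equal-length orthologs, where the
unweighted mean is the field convention. Skews with zero denominators are
reported as undefined (`NA`), never silently 0.

## RSCU classification and Table-1-style counts

Codon preference classes: over-represented (RSCU > 1.6), high bias
(1 < RSCU ≤ 1.6), unbiased (|RSCU − 1| ≤ 1e-9, exact ties only), low bias
(0.6 ≤ RSCU < 1), under-represented (RSCU < 0.6). Absent families yield
undefined entries (RSCU 0) that never enter preference counts. Per-gene
preferred-codon counts are computed by default from counts pooled across
species — the simplest reading of one-row-per-gene summaries — with a
per-species-mean alternative (`aggregation="per_species_mean"`) for
comparison. Heatmap ordering uses Euclidean distance with average linkage
(scipy), undefined cells imputed as 0 for distances only.

## Effective number of codons

Wright's estimator as generalized to arbitrary family structure (see
README for the formula). Choices for sparse data: families with fewer than
2 observations, or with a non-positive homozygosity estimate (possible at
tiny n), are excluded from their class mean; a degeneracy class with no
usable family is imputed at the neutral homozygosity 1/k and flagged in
the result, which keeps Nc defined for short genes such as ATP8. Nc is
clamped above by the code's sense-codon count, derived from the code (62
for table 5) rather than fixed at the standard code's 61. Because the
estimator carries Wright's 1/(n−1) small-sample correction, Nc is only
asymptotically invariant to scaling all counts by a constant; at a few
thousand codons the drift is well under 1%.

## Neutrality, PR2 and correlations

The neutrality plot regresses GC12 on GC3 (both on the 0–100 scale) by
ordinary least squares with no intercept constraint; at least 3 taxa and
non-constant GC3 are required. PR2 ratios use third positions of all sense
codons by default, consistent with how A3/T3/G3/C3 are defined for the
composition profile; the classical fourfold-degenerate-only variant is
available as an option. The correlation grid (overall composition and ENC
versus third-position composition) uses Pearson r with the two-sided
t-test p-value, stars at p < 0.05 (\*) and p < 0.01 (\*\*), no
multiple-testing correction; zero-variance cells are reported as `NO`.
With five taxa per gene these p-values rest on n = 5, which the pipeline
flags in its logs.

## Correspondence analysis

Implemented from first principles (chi-square standardized residuals +
SVD) on the RSCU matrix — RSCU rather than raw counts, following the
common practice in mitogenome codon-usage studies, even though CA's
derivation is count-based. Deletions before decomposition: stop-codon
columns, all-zero columns, all-zero rows (all recorded in the result);
single-codon families such as Met/Trp are retained unless all-zero. The
default analysis unit is per-gene with species as rows, which with five
species yields at most four axes; a pooled genes × codons mode is also
provided. Axes are oriented so the largest-magnitude column loading is
positive, making output deterministic across SVD backends. A matrix whose
rows are proportional to the column margins has zero inertia and returns
an all-zero result with a warning rather than raising. The test oracle is
an independent element-by-element eigendecomposition of S·Sᵀ, not a
library call.

## Synthetic CDS generator

The generator emulates the statistical structure the analyses are designed
to detect: a mutational third-position GC parameter θ, an AT-ending
selective preference s, and a switch controlling whether first/second
position composition is linked to θ. Each codon is drawn independently in
two stages:

1. the two-base prefix is sampled i.i.d. with GC probability θ12 — equal
   to θ in `linked` mode (GC12 tracks the mutational parameter with
   coefficient 1: the neutrality slope-1 regime) or pinned at 0.45 in
   `fixed` mode (selection-constrained, slope-0 regime);
2. given the prefix, a sense codon is chosen with weight
   `aa_freqs[aa] · m(b3) · exp(s·[b3 ∈ {A,T}])`, where m places probability
   θ on G/C third bases, split equally.

Amino-acid weights therefore act within prefix blocks: the realized
amino-acid composition is shaped by, not identical to, `aa_freqs`. This is
a deliberate trade — exact amino-acid marginals and exact positional GC
control are mutually exclusive, and positional GC control is what the
neutrality-plot validation needs. The codon distribution has a closed
form, so expected RSCU and expected GC3 are computed exactly
(`expected_rscu`, `expected_gc3_pct`); under table 5 every prefix block
pairs A/T- with G/C-ending codons symmetrically, giving
GC3 = θ/(θ + (1−θ)eˢ) exactly. Sampling draws codons i.i.d. from this
distribution, so simulated estimates carry plain binomial/multinomial
errors, which the validation uses as its error bounds.

Defaults are chosen to resemble an AT-rich insect mitogenome study: 5
species × the 13 named PCGs with realistic lengths (ATP8 ≈ 53 codons, ND5
≈ 562), θ = 0.2, s = 1.0, `fixed` GC12, code table 5, Leu/Ile/Ser/Met/Phe
enriched amino-acid weights. Under these defaults the fixture reproduces
the qualitative signatures such studies report: T > A > C > G overall,
T3 > A3 > C3 > G3, per-gene Nc in the low-to-mid 30s, and A/T-ending
codons over-represented. The generator does **not** model phylogenetic
correlation between species, indels, among-site rate variation, per-codon
fitness differences beyond the AT-ending term, or gene-specific
composition differences beyond length; passing the recovery tests
therefore shows the estimators are correct on i.i.d. codon data at these
sample sizes, not that real mitogenomes satisfy the model.

## Validation sizes and determinism

The property suite checks RSCU family sums on 1,000 random count vectors,
the CA eigen-oracle on 50 random 5×20 matrices (tolerance 1e-6), and the
composition identities on random CDS. Parameter recovery uses 50,000
codons for GC3 and RSCU coverage (3 standard errors), 30 species × three
400-codon genes for the neutrality sweeps (slope 1 ± 0.1 linked, 0 ± 0.1
fixed), and 20 replicate 10,000-codon genes per selection strength
s ∈ {0, 1, 2, 3} for Nc monotonicity. These sizes make every check fast
while keeping the statistical bounds comfortable. All randomness flows
through explicit integer seeds (numpy `default_rng`); the pipeline is
end-to-end deterministic — identical inputs and configuration reproduce
byte-identical TSVs.

## Known limitations

- ENC-plot expected curves (Nc versus GC3s) are not drawn; only scatter
  data are exported.
- Per-gene correlation grids and regressions on five taxa have very low
  power; the package reports them faithfully but they should be read as
  descriptive.
- GenBank ingestion trusts the annotated CDS coordinates; it does not
  re-annotate or validate gene boundaries.
- The CA of RSCU values (rather than counts) inherits the field's
  convention; its chi-square metric is then heuristic rather than exact.
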