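# Methods

This note documents the models, parameter choices and numerical decisions
behind `mixhet`, and what the synthetic-data experiments do and do not show
about real data.

## Clonality model

Two tumor regions of one patient either descend from a common malignant
precursor (clonal) or arose independently. Following the conditional
framework for somatic-profile clonality testing, the model conditions on the
set of *informative* loci — those mutated in at least one region — and treats
each informative locus independently. With marginal mutation probability
`p_j` for locus j (estimated from an external reference cohort), independence
of the two regions gives the conditional configuration probabilities
`q_sh = p/(2−p)` and `q_a = q_b = (1−p)/(2−p)`: a locus with at least one
mutation is shared with probability p/(2−p) when the two Bernoulli(p) calls
are independent.

The alternative is parametrized as a per-locus mixture with a single
clonality parameter ξ, interpreted as the probability that an informative
locus carries a precursor-derived (hence shared) mutation:
`P_sh = ξ + (1−ξ)q_sh`, `P_a = (1−ξ)q_a`, `P_b = (1−ξ)q_b`. This reduces to
the independence model exactly at ξ = 0 and makes the likelihood conjugate to
the pair generator, so parameter-recovery experiments have a well-defined
truth. The source framework does not print its alternative parametrization;
this one is our design choice and is isolated in
`clonality.conditional_config_probs`.

### Reference frequencies

`p_j = (c_j + α)/(n_ref + 2α)` with pseudocount α = 0.5 (Jeffreys-like), so
loci present in a test pair but absent from the reference cohort receive the
nonzero fallback `α/(n_ref + 2α)`. Values are clipped to (1e−6, 1−1e−6); the
clip floor also bounds simulated universes.

### Estimation and test

The LRT profile reduces to
`g(ξ) = Σ_shared log(ξ + (1−ξ)q_j) + n_priv·log(1−ξ)` (all other terms cancel
in 2(ℓ(ξ̂) − ℓ(0))). g is unimodal; we maximize by a coarse grid (step 0.01
over [0, 1−1e−6]) followed by golden-section refinement to ξ-tolerance 1e−6,
which a dense 10⁴-point grid oracle reproduces to 1e−4 on the LRT. With no
shared mutations every term carries a factor (1−ξ), so ξ̂ = 0 and LRT = 0
without optimization.

The null of the boundary LRT is nonstandard, so p-values are Monte Carlo:
each replicate redraws both regions' locus sets from the reference universe
as weighted samples without replacement (weights p_j; exponential-key
successive sampling), conditioning on the observed per-region mutation
counts, and refits. The add-one estimator
`p = (1 + #{LRT_sim ≥ LRT_obs})/(n_sims + 1)` never reports zero, so the
smallest attainable p is 1/(n_sims+1). Whether the original framework
conditions on per-tumor counts or total events, and samples with or without
replacement, is not stated in our source; the per-tumor / without-replacement
choice is ours and is what the type-I experiment validates.

### Operating characteristics (synthetic)

* **Type-I error**: 500 independent pairs with 100 mutations per region over
  a Beta(0.5, 50) universe of 10,000 loci, n_sims = 499. Null pairs are drawn
  with the same per-tumor sampler the Monte-Carlo null uses, which makes
  observed and simulated LRTs exchangeable, so rejection at α = 0.05 is
  calibrated by construction up to ties and binomial noise (observed 0.044).
  Note that pairs generated instead from the conditional mixture at ξ = 0
  with a *fixed total* event count are a different conditioning: at 100
  events over a universe whose natural informative count is ≈195, the
  expected shared count is about twice the fixed-margin null's, and the test
  would be anticonservative against that generator.
* **Recovery**: at 200 events/pair the mean ξ̂ over 200 replicates is within
  ±0.005 of ξ ∈ {0.2, 0.5, 0.8}.
* **Power**: measured at 4 events/pair (n_sims = 199). At hundreds of
  rare-locus events any shared mutation is essentially decisive and power
  saturates at 1 for every ξ ≥ 0.2, so the low-information regime is the one
  in which the power curve is informative; there it increases strictly
  (≈0.62 → 0.94 → 0.99).

## Phylogeny statistics

Mutation identity for cross-region matching is allele-level
(chrom:pos:ref:alt), not gene-level, so distinct substitutions at one codon
are private to their regions. The three-taxon tree over {NORMAL, UC, SqD}
(NORMAL carries none of the somatic mutations) is computed analytically:
Hamming distances over the union presence matrix are d(N,U) = n_sh + n_a,
d(N,S) = n_sh + n_b, d(U,S) = n_a + n_b, and the three-point decomposition
returns b_U = n_a, b_S = n_b, b_N = n_sh exactly — no tree-search engine, the
topology is fixed by design. Phylogenic ratio is private/shared per region,
with an infinity sentinel (not an error) at zero shared so downstream median
and fold comparisons tolerate it. Concordance is shared-over-union per pair,
reported as percent, with the cohort value the unweighted mean of per-pair
percentages; "average concordance" is ambiguous between pooled and per-pair
readings, so the choice is isolated in `phylo.concordance`. TMB is
nonsynonymous count / covered megabases; footprints differ per sample, so
`covered_mb` is a required input, never a constant.

## Single-sample enrichment and subtyping

The literature names single-sample GSEA without fixing a variant; we use a
rank-weighted area statistic with weight `(G − r + 1)^α` at rank r, α = 0.25
by default, and lexicographic gene-id tie-breaking so scores are
deterministic. At α = 0 the score is a pure rank statistic, invariant under
any strictly monotone transform of the expression values, and antisymmetric
under rank reversal (which is why a regulon whose negative targets mirror its
positive targets scores exactly twice the single-set score). The
implementation is checked to 1e−9 against an independent step-by-step
running-sum enumeration. Matrix-level normalization divides all scores by the
global max−min; this bounds scores in [−1, 1] exactly when raw scores span
zero, the typical case for signature collections containing both up- and
down-concentrated sets.

Centroid construction selects, per class, the top-k genes by the magnitude of
a shrunken one-vs-rest t statistic `t_g = (mean_in − mean_out)/(s_g + s0)`
with pooled SD s_g and s0 = median pooled SD (the centroid-selection
procedure we mirror does not print its statistic; this shrinkage is our
choice and is isolated in `build_centroids`). k defaults to 500 genes per
class; centroids are within-class means over the pooled panel.
Classification distance is 1 − Pearson correlation over the intersection of
panel and sample genes (silent intersection, error below 2 shared genes —
cross-platform panels rarely match exactly), with lexicographic label
tie-breaks and an explicit error on zero-variance profiles.

DE threshold filtering uses strict inequalities (log2FC > cut, FDR < cut),
matching "fold change greater than" phrasing; a gene exactly at the boundary
is excluded.

## Regulatory windows and overlap

Peak anchor = summit when provided, else the interval midpoint (the anchor
convention is not fixed by our source; it is a parameter of the
implementation). Promoter = anchor within ±2 kb of a TSS; enhancer = anchor
within the strand-oriented span from 50 kb upstream of the TSS to 5 kb
downstream of the TES (for − strand genes upstream extends to higher
coordinates); intergenic otherwise. The promoter window is a subset of the
enhancer span, so promoter takes precedence and the three categories
partition any peak set; assigned gene is the nearest TSS among genes
qualifying at the awarded category. Peaks on chromosomes absent from the gene
models are intergenic with a warning (scaffold mismatch is common and
non-fatal). The annotator is validated against a per-base oracle that paints
every base of small random genomes by literal rule application.

"Within 5 kb" factor/mark proximity is measured edge-to-edge (gap 0 for
touching or overlapping intervals) — the most permissive literal reading,
parameterized via `max_gap_bp`. Proportions are over the union count
(overlapping counted once, from the mark side) and sum to 1. TSS-proximity
filtering keeps regions whose anchor is within 10 kb (unsigned) of any TSS.
Signal clustering delegates to k-means++ / Lloyd (scikit-learn) with 10
restarts and a fixed seed, relabeling clusters 1..k by decreasing mean
signal so "cluster 1" is always the high-signal group.

## Exact statistics

Fisher's exact 2×2 test enumerates the hypergeometric family in log-space
(gammaln) and sums tables with probability ≤ observed × (1 + 1e−7) — the
minimum-likelihood two-sided convention of mainstream statistical software.
The signed-rank test drops zero differences, uses mid-ranks for ties, and is
exact for n ≤ 25 via a subset-sum DP on doubled ranks (doubling keeps
half-integer mid-ranks integral); beyond 25 it switches to a tie- and
continuity-corrected normal approximation. The rank-sum test uses the
corrected normal approximation; Spearman is the Pearson correlation of
mid-ranks with a t-distribution p-value. Benjamini-Hochberg is step-up with
enforced monotonicity; Bonferroni is min(1, m·p). All of these are
cross-checked in the tests against independent enumeration oracles and
against scipy/statsmodels.

## Synthetic data: what it does and does not emulate

Reference universes draw `p_j` i.i.d. from Beta(0.5, 50) clipped to
(1e−6, 0.5] — a long right tail resembling a hotspot spectrum, mean ≈ 0.0099
— with an optional hotspot mixture multiplying a fraction of loci by a
constant factor. Pair simulation selects informative loci without replacement
with weights `p(2−p)` (the at-least-one-mutated selection probability) and
assigns configurations from the mixture, so the generator and the likelihood
agree by construction; locus sampling is without replacement because a locus
can be mutated at most once per pair in the data model. Expression matrices
are log-scale Gaussian (baseline N(8,1)) with disjoint subtype signatures
shifted by +3 and noise sd 0.5 — a deliberately strong, clean separation.
Landscape simulation places one region anchor per wide genome tile so planted
overlap and annotation classes cannot interact across regions.

Because the generators match the models' assumptions, passing recovery tests
demonstrates the correctness and calibration of the implementations, not
robustness to real-data violations: no copy-number or purity variation, no
calling error, no inter-locus dependence (kataegis, signatures), no
batch/platform effects in expression, and no irregular peak geometry. The
headline cohort-scale numbers of the motivating study depend on
controlled-access sequencing data and are therefore demonstrated
qualitatively on synthetic cohorts only.

## Problem sizes and determinism

The standard experiment sizes are: 500 pairs × 499 null replicates for the
type-I study; 200 replicates per ξ for recovery (200 events) and power
(4 events, 199 replicates); 1,000 pairs for the branch-identity property;
100 instances for the enrichment oracle; 50 genomes for the annotation
oracle; 1,000 regions for overlap recovery. These sizes put the Monte-Carlo
standard errors well inside the asserted tolerances while keeping a full run
of the suite and the acceptance script in the minutes range on one CPU.
Every stochastic routine takes an explicit seed and spawns child streams via
`numpy.random.SeedSequence`; identical seeds give bit-identical outputs
everywhere, including the CLI (which also writes a parameter manifest per
run).
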