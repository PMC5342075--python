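# Methods

This note documents the statistical models, the synthetic-data
generators, the numerical choices and the design decisions behind
`mirpath`, in the spirit of a package vignette.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Moderated differential expression

With triplicate arrays per cell line, per-feature variance estimates on
4 residual degrees of freedom are unstable; the empirical-Bayes
hierarchical model borrows strength across features.  The model:
conditional on σ²_g, the residual variance s²_g ~ σ²_g·χ²_d/d, and the
precision has a scaled chi-square prior, 1/σ²_g ~ χ²_{d₀}/(d₀·s₀²).
The posterior-mean variance s̃²_g = (d₀·s₀² + d·s²_g)/(d₀ + d) yields
the moderated t with d₀ + d null degrees of freedom.

Hyperparameters are fitted by the method of moments on z = log s²:
E[z] and Var[z] are linear in digamma/trigamma evaluated at d/2 and
d₀/2, so d₀ solves trigamma(d₀/2) = Var̂(e) − trigamma(d/2) with
e_g = z_g − digamma(d/2) + log(d/2).  The trigamma inverse is computed
by the standard Newton scheme on the tetragamma update, started from
the asymptotic value 0.5 + 1/y; convergence is monotone.  Numerical
policy:

* non-positive excess dispersion ⇒ d₀ = ∞ (complete shrinkage, normal
  reference); d₀ > 10⁶ is also reported as ∞;
* a single feature ⇒ d₀ = 0 (no shrinkage; ordinary pooled t);
* all-zero residual variances raise an estimation error naming the
  likely cause (constant or duplicated samples) rather than returning
  degenerate statistics.

Contrasts are simple two-group comparisons by default.  The original
three-group design can share one variance across all groups
(`shared_variance=True` pools within-group residuals, d = N − G); the
two-group default is documented since the source analysis does not
state which linear model its fits used.  The implementation is
cross-checked in the test suite against Bioconductor limma on a
heteroscedastic fixture (hyperparameters, t and P agree to ~1e-8
relative) and against a directly coded pooled t in the d₀ = 0 limit
(1e-12 absolute).

**Holm adjustment** is the step-down procedure
adj_(i) = min(1, max_{j≤i}(m−j+1)·p_(j)) applied in ascending order
with stable (index-ordered) tie-breaking, returned in input order; it
dominates Bonferroni elementwise and is checked against statsmodels.

**Classification** uses strict inequalities — FC > 1.5 (or < 1/1.5)
and P < 0.05 — so a feature exactly at a threshold is not significant.
Both raw and Holm-adjusted P are emitted: volcano-plot-style outputs
conventionally use the raw P, heatmap/table-style reporting the
adjusted one; `use_adjusted` selects.

## Signature sets

The three contrasts' significant sets are partitioned into the seven
exact Venn cells; aggregates are derived, not stored: the
"E₂-independent growth" set is the intersection of the two
model-vs-reference contrasts, model-specific sets are set differences,
and the direct-contrast-only cell collects candidates found only by
comparing the two resistant models.  All seven cells are kept explicit
so any aggregate can be recomputed; the identity
|A∪B| = |A| + |B| − |A∩B| and the per-contrast decompositions are
property-tested.

z-scores use the sample standard deviation (n−1); zero-variance rows
are excluded and reported rather than emitting NaNs.  Within each Venn
cell (fixed display order: triple intersection, shared pair, then the
modelA block, modelB block, direct-only block) features are ordered by
complete-linkage agglomeration on d = 1 − Pearson r across all retained
samples; the distance matrix is symmetrized against floating-point
asymmetry and clipped at 0.  Merge heights are monotone for complete
linkage; the agglomeration is verified against a brute-force
implementation that recomputes the full cluster-distance matrix at
every step (≤ 7 features).  A fourth sample group (e.g. a short-term
treatment arm) is simply excluded via `ExpressionStudy.subset_groups`;
its contrast remains available as an ordinary two-group comparison and
its subtraction from other signatures is plain set difference.

## Target mapping

Interaction records carry the prediction tool's context-score
percentile and a CLIP support count.  "CLIP-confirmed" is support
count ≥ 1 (no count threshold is defined by the convention the filter
mirrors), and the percentile cut is strict (> 50 by default), matching
the "> 50 percentile" convention.  The package consumes scored
interaction tables; it does not compute target predictions itself, and
gene identifiers are opaque symbols (no alias resolution).  Filtering
is idempotent and monotone in the percentile threshold; target sets of
a miRNA set are plain unions and monotone in the set.

## Pathway enrichment

Fisher over-representation is the one-sided hypergeometric tail
P(X ≥ k) with counts (k overlap, K pathway∩background, n targeted set,
N background).  The default background is the *targetable* universe —
genes with at least one filtered interaction — rather than the whole
genome; this already removes part of the bias toward long, site-rich
3′UTRs, and is switchable.

The permutation null addresses the remainder of that bias at the miRNA
level: B random subsets of the expressed miRNAs, of the same size as
the signature, are mapped through the filtered interaction table and
the per-pathway statistic recomputed; p = (1 + #{stat_b ≥ stat_obs})/(B+1)
with the add-one convention so p ∈ [1/(B+1), 1].  Defaults: B = 999,
statistic = targeted-gene count.  The Fisher P of the resampled set is
available as an alternative statistic; because the count statistic is
integer-valued, ties make its permutation p conservative (never
anti-conservative), while the near-continuous Fisher-P statistic
attains the nominal rejection rate — the type-I calibration test
asserts the band on the Fisher-P statistic and conservatism of the
count statistic for exactly this reason.  A constructed "sticky
pathway" instance (genes targeted by half of all miRNAs) demonstrates
the bias the null exists to absorb: the hypergeometric test flags it
for a majority of random miRNA sets while the permutation test stays
near nominal.  miRNA sets and the expressed universe are canonically
sorted before sampling, so results are invariant to input record order
at fixed seed.  Exhaustive enumeration of all subsets replaces sampling
on demand (used by tests on 5-choose-2 instances).

Pathway P-values are deliberately *not* multiplicity-corrected by
default (matching the reporting convention of the analysis this
pipeline reimplements); Holm/BH are available on the result columns.
Up/down stratification reruns both engines per stratum and enforces
disjoint strata.

## Pathway networks

Nodes are pathways with enrichment P below 0.05 (tiers at 0.001, 0.01,
0.05 kept as categorical attributes; rendering is presentation-layer).
The Jaccard edge weight is computed on the *regulated* pathway gene
sets — pathway members actually targeted by the signature — because the
network describes what the signature touches; full-membership Jaccard
is a flag, since the original convention is not stated.  Zero-overlap
pairs get no edge, so edge weights live in (0, 1].  Network comparison
pools each network's regulated sets and partitions the union into
model-specific and shared genes, with a per-gene frequency (number of
pathway nodes containing it across both networks) for ranking.

## Clinical layer

* **log₂CPM**: log₂((c + 0.5)/(L + 1)·10⁶) — the standard pseudocount
  convention; the source transform is stated only as "log2CPM".
  Library sizes are carried explicitly (simulated counts cover a
  miRNome subset, so column sums would understate depth).
* **Co-expression**: Spearman rho (average ranks on ties), complete
  linkage on 1 − rho; constant rows are excluded with a warning.
* **Subtype comparisons**: Kruskal–Wallis globally, pairwise two-sided
  Wilcoxon rank-sum, raw P mapped to the star tiers
  (< 0.05/0.01/0.001/0.0001).  The non-parametric choice is a design
  decision (the convention shows only star tiers); pairwise P are
  unadjusted to match that reporting.
* **Kaplan–Meier / log-rank / Cox**: product-limit estimator;
  two-group log-rank from hypergeometric moments at distinct event
  times; Cox partial likelihood for one binary covariate maximized by
  Newton–Raphson with Breslow tie handling (the simplest well-defined
  choice), Wald CI from the observed information.  Monotone likelihoods
  are capped at |β| = 15 with a warning.  All three are validated
  against lifelines (on tie-free data, where Breslow and Efron
  coincide), a risk-set hand enumeration, and a grid-search maximizer.
* **Survival cutpoints**: a maximally selected log-rank statistic —
  candidate thresholds are observed expression values whose empirical
  CDF lies in the (0.1, 0.9) quantile window; the standardized log-rank
  score is computed for every candidate by one vectorized pass over
  distinct event times; the |z|-maximizing threshold is selected
  (ties: smallest).  Because maximizing over splits invalidates the
  naive minimum P, selection-adjusted inference permutes expression
  against outcomes and re-maximizes (p_adj with the add-one
  convention, B = 999 by default).  This single-split formulation
  stands in for a conditional-inference tree: one split is all the
  stratification uses, and the permutation maximum provides the
  selection correction that the tree's conditional inference would.
  The null-calibration test shows the adjusted P at its nominal 5%
  while the naive minimum-P rejects ~40–50% of null datasets.

## Synthetic data: what it emulates, and what it does not

`StudyConfig` defaults mirror the profiled design: three groups
(reference, modelA, modelB) × 3 replicates, log2-scale Gaussian
replicate noise (sd 0.3), detection floor 0.3 applied by clipping (so
"silenced" features sit at ~0.3–1.0 like the printed mega-cluster
means), and planted additive shifts.  Cluster co-regulation uses a
shared Gaussian factor: noise = √ρ·factor + √(1−ρ)·ε gives exact
pairwise correlation ρ — the simplest construction achieving a target
r.  The zero-noise limit is permitted (noise_sd ≥ 0) so exactness
properties are directly testable.

`CohortConfig` defaults mirror a TCGA-like breast cohort: 746
patients, PAM50 subtype proportions from the 513-patient annotated
subset (LumA 0.493, LumB 0.224, Basal 0.168, HER2 0.084, Normal
0.031), library sizes 0.5–2 million, negative-binomial counts with
dispersion 0.3 (miRNA-Seq overdispersion), patient-level log2
expression spread 1.5.  Survival is exponential (baseline 0.08/year)
under proportional hazards.  Two deliberate generator choices:

* the planted dichotomy is defined on the **realized** log₂CPM (true
  library sizes), not on a latent expression — the signal the method
  must find is exactly encoded in the data it sees, so recovery tests
  measure the method, not count-noise attenuation;
* planted-survival miRNAs are pinned at a readily quantifiable
  abundance (base log₂CPM 6) for the same reason;
* the censoring exponential is calibrated against the cohort's
  *marginal* hazard, so `censoring_rate` ≈ the realized censored
  fraction even when planted hazards raise the event rate (0.65 gives
  ~35% events under a planted HR 3 dichotomy).

`generate_planted_bundle` wires a complete study: model-specific
signatures (one including a 10-member near-floor silenced cluster
overexpressed ~6 log2 units in modelB), interaction tables with
round-robin coverage so every planted pathway gene is targeted by its
signature, 11 pathways planted on the shared gene pool, model-specific
and null pathways, plus sub-threshold decoy records exercising the
filters.  The construction makes the expected network gene partition
derivable in closed form, so end-to-end recovery can be asserted
exactly.

What the generators do **not** emulate: probe-level effects, batch
effects and array normalization artefacts; correlated multi-miRNA
targeting structure beyond the planted pools; non-proportional hazards,
competing risks or informative censoring; subtype-expression coupling.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated models, not robustness to those real-data
complications.

## Problem sizes in tests and the acceptance script

Simulation-based checks use deliberately modest sizes chosen to give
stable Monte-Carlo assertions: 100-seed batches for recovery/coverage
claims, 200 seeds for cutpoint calibration (B = 199 permutations, so
the nominal rejection probability at α = 0.05 is exactly 10/200), 500
null pathway tests for permutation calibration, n = 750 cohorts for
hazard recovery, and the full N ≤ 15 sweep for the exact Fisher
oracle.  Binomial 99% bands around nominal rates are used for all
calibration assertions.

## Known limitations

* The moment estimator for (d₀, s₀²) has no robustification against
  variance outliers (hypervariable features would inflate s₀²).
* Cox supports a single binary covariate — sufficient for
  high-vs-low stratification, not multivariable adjustment.
* The cutpoint search is a single split; recursive partitioning,
  multiple-split trees and minimum-node-size tuning are out of scope.
* GMT parsing follows the two-header-column convention strictly;
  pathways must be non-empty and duplicate-free.
* Enrichment treats miRNA sets as unweighted; fold-change-weighted or
  ranked variants (GSEA-style) are out of scope.
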