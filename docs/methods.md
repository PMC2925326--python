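# Methods

## Normalization

Quantile normalization forces every sample's value distribution onto a
common reference, here the across-sample mean of the order statistics
(the standard choice).  Ties within a sample receive the mean of the
reference values at the tied ranks, so within-sample rank order is
preserved exactly and the transform is idempotent to floating
precision.  Normalization is applied per tissue: SAT and VAT are
normalized independently, as depot-level distribution differences are
themselves of interest downstream.  Downstream correlations are
computed on the normalized intensities on their natural (linear) scale;
rank-based statistics (Spearman, Mann–Whitney) are invariant to any
monotone rescaling, and Pearson module correlations on quantile-
normalized data are the field's convention, so no log transform is
applied by default.

Missing expression values are rejected rather than imputed: arrays are
complete by construction, and a hole in the matrix indicates a parsing
problem, not a biological one.

## Sample quality control

Samples are screened on four criteria: median probe intensity
(z-score across samples, default cut −3), mean Pearson correlation with
the other samples of the same tissue (default minimum 0.80), distance
on the first two principal components of the sample × probe matrix
(default 4 SD), and — when a housekeeping probe list is supplied — the
z-score of the mean within-sample rank of those probes (default 4).
All metrics are computed once on the full matrix and every enabled
criterion applied in a single pass, so the outcome does not depend on
removal order.  The thresholds are conventions, not reproductions of
any published values (none were published), and all are configurable;
tightening a threshold can only grow the flagged set.

## Module construction

The builder maintains a set of items — initially the probes (zero-
variance probes are excluded, their correlation being undefined) — and
repeats:

1. find the maximum Pearson correlation over all current item pairs,
   considering positive values only;
2. stop if that maximum is below `r_stop` (default 0.65);
3. otherwise merge the arg-max pair into a new item whose profile is
   the unweighted per-sample mean over *all* constituent probe rows
   (`probe_mean`; a WPGMA-like `pair_mean` that averages the two merged
   profiles is available, and differs for unequal sizes), and record
   the merge.

Low-expression probes are deliberately not filtered: noise is random
and does not co-express, so it cannot contaminate modules, whereas any
expression cut-off would be arbitrary.  Anti-correlated probes are
never merged because they may represent mutually exclusive processes.
Merge correlations are **not** monotone decreasing — averaging denoises
profiles, so a later merge may exceed an earlier one; the only
guarantees are that every recorded merge has r ≥ `r_stop` and that at
termination no positive pair reaches it.

Ties at the maximum (exactly equal correlations, which arise with
duplicated probes) are broken toward the pair with the lexicographically
smallest (older item, newer item) creation indices, making runs
deterministic.

Two execution strategies share one correlation kernel: a `naive`
reference that recomputes the full pairwise table every iteration, and
a `cached` strategy that keeps the table and refreshes only the rows a
merge touches.  The kernel evaluates one scalar dot product per pair
(rather than one matrix–vector product per row) because BLAS gemv
accumulation can differ in the final ulp with the stack shape, and the
two strategies are required to agree bit-for-bit — which the test suite
asserts on hundreds of random instances.  The cached strategy handles
panels of a few thousand probes in minutes on one core.

Modules are filtered to those whose *distinct gene* count (probes
collapse by symbol; unannotated probes each count as their own gene)
reaches `min_genes` (default 5).

## Differential expression

Each probe shared by the two depot panels gets a two-sided Wilcoxon
Mann–Whitney test: exact enumeration when both group sizes are ≤ 8,
otherwise the normal approximation with mid-rank tie correction and
continuity correction (scipy's implementation).  The fold change is the
ratio (≥ 1, with a direction label) of the two group means of
linear-scale normalized intensities; medians are available as an
option.  Bonferroni correction divides α by the number of probes
actually tested.  Fold-change bins (> 1.5, > 10 by default; strict
inequalities) count only Bonferroni-significant probes — a fold change
without significance is noise.  The random stratified selection used to
pick validation candidates sorts significant genes (best-p probe per
gene) by fold change descending, splits them into 10 contiguous bins as
equal as possible (remainder spread over the first bins), and draws one
gene per bin with a seeded generator.

## Trait association

Module profiles are tested against traits with Spearman rank
correlation (Pearson on mid-ranks; two-sided p from the t
approximation with n − 2 df); pairs with a missing value are dropped
per test.  Binary gender is 0/1-coded and sent through the same rank
machinery.  The significance threshold is α / (modules tested × traits
tested); with the study's 67 modules and 14 traits that is
0.05/938 = 5.33 × 10⁻⁵.

Conditional re-analysis approximates conditional Spearman correlation
by residualization: all variables are mid-rank transformed over
complete cases, profile and trait ranks are residualized on the
confounder ranks by least squares with intercept, and the residual
Pearson correlation is tested with n − 2 − k df.  With no confounders
this reduces exactly to the marginal test.  A confounder that
duplicates the tested variable leaves a numerically zero residual; the
association is then reported as absent (ρ = 0, p = 1) with a warning
rather than as an error, so that scanning many (pair, confounder-set)
combinations never aborts mid-table; a request in which *every*
combination degenerates this way is an error.  For single-trait
confounder sets the reverse direction (confounder as outcome, adjusted
for the original trait) is reported too — this is the argument pattern
that distinguishes "HDL drives the module" from "BMI drives the
module".

## Gene-set overlap

The one-sided overrepresentation p for two sets of sizes |A| and |B|
overlapping in k genes from a universe of N is the hypergeometric upper
tail P(X ≥ k), computed as a log-space sum of log-pmf terms so that
values far below double underflow (10⁻⁴⁰ and beyond) remain exact in
log₁₀.  The default universe is 20,000 unique genes, overridable.  A
two-sided Fisher's exact alternative is available behind a flag.
Module cross-tabulations collapse modules to distinct-gene sets and
tabulate the ten largest per side, with a per-cell tail p.

## The synthetic cohort generator

The generator emulates the statistical structure of the study — not
any real array's marginal distributions.  Per sample i and probe j of
module m:

    x_ij = μ_j + a f_mi + ε_ij,  f_mi ~ N(0,1),  ε_ij ~ N(0, σ²)

so the population within-module Pearson correlation is a²/(a²+σ²)
(exposed as a closed form and verified against Monte-Carlo runs).
Probe baselines μ_j are Uniform(base ± spread): baselines do not move
any correlation, but they are what makes inter-sample correlations high
(as on real chips) and gives quantile normalization a realistic
target.  The uniform law specifically keeps baseline spacings small
relative to noise so that no probe holds a constant rank across
samples — on a scaled-down panel a heavy-tailed baseline would let the
extreme probe map to the identical reference value in every sample,
a degenerate constant row that full-size arrays never produce.

Traits linked to a module ride on its factor, t_i = b f_mi + η_i;
confounded trait pairs share an added Gaussian component chosen to give
the requested marginal correlation; gender is an independent fair coin;
non-gender traits have 2% missing values by default.  Depot
differential expression is a multiplicative fold change applied to a
probe's designated depot, matching the study's fold-change vocabulary.

Defaults are the study conditions: 70 samples per depot, ~520 probes,
three planted modules (40/15/8 probes) at loading 0.9 with σ = 0.43
(within-module r ≈ 0.81, comfortably above the 0.65 stop), trait
couplings b = ±0.8 with unit trait noise (population profile–trait
Spearman ρ ≈ 0.60), glucose–TG/HbA1c and BMI–insulin confounding, and
1.8-fold / 12-fold shift classes in both directions.

What the generator does *not* emulate — bead-level noise, probe GC
effects, probe–gene multiplicity beyond a uniform factor, non-Gaussian
trait marginals, batch structure — bounds what passing tests show:
they demonstrate the algorithms are correct and calibrated on data with
the designed correlation structure, not that any particular real
dataset will yield the study's module counts.

## Numerical choices and scaled-down problem sizes

Correlations are clipped to [−1, 1]; near-constant profiles (L2 norm
of the centered vector < 10⁻¹²) correlate as zero; expression TSVs are
written with `%.17g` and parsed with correctly-rounded converters so
write-then-read round-trips are bit-exact.  Validation suites run at
desk scale, chosen to finish in seconds while keeping each check
well-powered: 200 random instances of ≤ 50 probes for
builder/reference equivalence, 50 cohorts at the default design for
recovery and trait-link power, 1000 null probes at 30 + 30 samples for
Mann–Whitney calibration, and a 10-gene universe for exhaustive
hypergeometric enumeration.

## Known limitations

- At a population profile–trait Spearman of 0.60 with n = 70, power
  against the 5.33 × 10⁻⁵ family-wise threshold is ~93% per cohort, so
  a cohort's planted link occasionally escapes the Bonferroni net; the
  recovery of module *membership* under the default design is far more
  reliable.
- Rank-residualization is an approximation to true conditional
  Spearman correlation; with strongly non-monotone confounding it can
  under-adjust.
- Quantile normalization over very small panels (tens of probes) has a
  coarse reference and can induce spurious neighbour correlations; the
  pipeline is intended for panels of hundreds of probes or more.
- The greedy merger is order-deterministic but, like all greedy
  agglomeration, not globally optimal; a pair merged early cannot be
  re-assigned.
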