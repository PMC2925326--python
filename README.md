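# adipomod

Co-expression module discovery and metabolic-trait association for
two-depot adipose transcriptomics.

## The problem

In severely obese individuals, expression of large groups of genes in
subcutaneous (SAT) and visceral (VAT) adipose tissue tracks plasma
metabolic traits — HDL cholesterol, glucose, insulin — and those groups
are heavily enriched in immune genes, consistent with macrophage
infiltration of adipose tissue.  Analysing tens of thousands of
microarray probes one at a time against a dozen traits is hopeless at
n ≈ 70; grouping co-expressed probes into *modules* and testing the
module profile instead is both more powerful and more interpretable.

`adipomod` implements that analysis as a tested, reusable pipeline:

1. **Normalization & QC** — per-tissue quantile normalization (every
   sample mapped onto the mean order-statistic reference) and
   per-sample screening on median intensity, inter-sample correlation,
   housekeeping-probe behaviour, and principal components.
2. **Differential expression** — per-probe two-sided Wilcoxon
   Mann–Whitney tests between depots, Bonferroni correction, fold-change
   binning (>1.5-fold, >10-fold), and the random stratified selection of
   qPCR validation candidates.
3. **Module construction** — the core algorithm: iteratively merge the
   most strongly *positively* correlated pair among all current items
   (probes and modules), recompute the merged profile as the unweighted
   mean of its member probes, and stop when the best remaining pair has
   Pearson r < 0.65.  Negative correlations never merge.  Modules are
   then filtered to those with ≥ 5 distinct genes.
4. **Trait association** — Spearman rank correlation ρ of each module
   profile with each clinical trait, significant when
   p < α / (n_modules × n_traits); significant pairs are re-tested by
   rank-based partial correlation given candidate confounders (and in
   the reverse direction, to identify which trait drives a module).
5. **Gene-set overlap** — one-sided hypergeometric tails
   P(X ≥ k) for overlaps between gene sets in a 20,000-gene universe,
   summed exactly in log space (p ≈ 10⁻⁴⁰ stays representable), plus the
   cross-tabulation of the largest SAT vs VAT modules.
6. **Synthetic cohorts** — a generator that plants latent-factor
   modules (x_ij = μ_j + a·f_i + ε_ij, within-module
   r = a²/(a²+σ²)), trait couplings, correlated confounders, and
   depot fold-change classes, with full ground truth for every stage.

## Worked example

```python
import adipomod as am

cohort = am.generate_cohort(am.SyntheticDesign(), seed=1)
sat = am.quantile_normalize(cohort.sat)
modules = am.build_modules(sat)
for mod in sorted(modules.multi(), key=lambda m: -m.n_probes):
    print(f"{mod.module_id}: {mod.n_probes} probes, "
          f"first merge r = {mod.merge_history[0][2]:.3f}")
assoc = am.associate_modules(modules, cohort.traits, alpha=0.05,
                             expression=sat, bonferroni_tests=67*14)
print(f"Bonferroni threshold: {assoc.threshold:.3g}")
print(assoc.significant_pairs()[["module_id", "trait", "n", "rho", "p"]]
      .to_string(index=False))
res = am.overlap_from_counts(13, 31, 103, universe=20_000)
print(f"overlap 13/31 vs a 103-gene module, N = 20000: p = {res.p:.2e}")
```

prints

```
M60: 40 probes, first merge r = 0.832
M48: 15 probes, first merge r = 0.858
M8: 8 probes, first merge r = 0.876
Bonferroni threshold: 5.33e-05
module_id           trait  n       rho            p
      M48         glucose 70  0.554125 6.474549e-07
      M60 HDL_cholesterol 69 -0.481366 2.824668e-05
overlap 13/31 vs a 103-gene module, N = 20000: p = 1.56e-22
```

The three planted modules (40, 15 and 8 probes) are recovered exactly;
the 40-probe module is negatively associated with HDL cholesterol and
the 15-probe module positively with glucose, each far below the
family-wise threshold 0.05/(67 × 14) = 5.33 × 10⁻⁵ (n = 69 for the HDL
test because one trait value is missing and pairs are complete-case).
The last line is the hypergeometric tail for 13 macrophage-specific
genes out of 31 landing in a 103-gene module.

A command-line interface mirrors the stages
(`adipomod simulate | normalize | qc | diffexpr | build-modules |
associate | conditional | overlap | export-network | run`); `adipomod
run --seed 1 --outdir out` executes the whole pipeline on a synthetic
cohort and writes every table plus a run manifest.

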