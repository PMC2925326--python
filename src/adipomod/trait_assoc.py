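"""Module-trait association and confounder-conditional re-analysis.

Module profiles (per-sample mean expression of the module's probes) are
tested against clinical traits with Spearman rank correlation, with a
Bonferroni family over all modules x traits tested.  Significant pairs
are then re-examined conditionally: ranks of profile and trait are
residualized on the ranks of candidate confounders and the correlation
of residuals is tested — an approximation to conditional Spearman
correlation.  The reverse direction (confounder as outcome, adjusting
for the original trait) is tested as well, which is what lets one argue
that a trait, rather than its correlates, drives a module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, TraitTable
from .module_builder import Module, ModuleSet, module_profiles

logger = logging.getLogger(__name__)

MIN_PAIRS = 5


@dataclass
class AssociationResult:
    """All module x trait Spearman tests plus the Bonferroni verdicts.

    ``table`` columns: module_id, trait, n, rho, p, threshold, significant.
    """

    table: pd.DataFrame
    profiles: pd.DataFrame     # module x sample
    alpha: float
    threshold: float

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


@dataclass
class ConditionalResult:
    """Partial-correlation re-analysis of the significant pairs.

    ``table`` columns: module_id, trait, confounder_set, confounders,
    direction (forward | reverse), partial_rho, partial_p, verdict
    (robust | confounded at level 0.05).
    """

    table: pd.DataFrame
    level: float = 0.05


# ---------------------------------------------------------------------------
# Rank-correlation primitives
# ---------------------------------------------------------------------------

def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on mid-ranks) and two-sided p (t with n-2 df).

    Pairs with a missing value in either vector are dropped; at least
    5 complete pairs are required; a constant vector is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a ranked vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, confounders=()) -> tuple[float, float]:
    """Rank-based partial correlation of x and y given confounders.

    All variables are mid-rank transformed over complete cases; the x
    and y ranks are residualized on the confounder ranks by least
    squares (with intercept); rho is the Pearson correlation of the
    residuals and p comes from a t distribution with n - 2 - k df.

    With an empty confounder list this reduces exactly to
    :func:`spearman_correlation`.  When either residual is numerically
    zero (a confounder duplicates the variable) the association is
    reported as absent: (rho=0, p=1) with a warning.
    """
    confs = [np.asarray(c, dtype=float) for c in confounders]
    if not confs:
        return spearman_correlation(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    for c in confs:
        if c.shape != x.shape:
            raise ValueError("confounder length mismatch")
        ok &= np.isfinite(c)
    k = len(confs)
    n = int(ok.sum())
    if n < k + MIN_PAIRS:
        raise ValueError(f"need at least {k + MIN_PAIRS} complete cases, got {n}")
    xr = stats.rankdata(x[ok])
    yr = stats.rankdata(y[ok])
    C = np.column_stack([np.ones(n)] + [stats.rankdata(c[ok]) for c in confs])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("collinear confounders (rank-deficient design)")
    beta_x, *_ = np.linalg.lstsq(C, xr, rcond=None)
    beta_y, *_ = np.linalg.lstsq(C, yr, rcond=None)
    rx = xr - C @ beta_x
    ry = yr - C @ beta_y
    scale = max(np.linalg.norm(xr - xr.mean()), np.linalg.norm(yr - yr.mean()), 1.0)
    if np.linalg.norm(rx) < 1e-8 * scale or np.linalg.norm(ry) < 1e-8 * scale:
        logger.warning("degenerate residual in partial correlation; reporting rho=0")
        return 0.0, 1.0
    rho = float(np.dot(rx - rx.mean(), ry - ry.mean())
                / (np.linalg.norm(rx - rx.mean()) * np.linalg.norm(ry - ry.mean())))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough degrees of freedom")
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) >= 1.0:
        return rho_c, 0.0
    t = rho_c * np.sqrt(df / (1.0 - rho_c * rho_c))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho_c, p


# ---------------------------------------------------------------------------
# Module-level association
# ---------------------------------------------------------------------------

def associate_modules(
    profiles: pd.DataFrame | ModuleSet,
    traits: TraitTable,
    alpha: float = 0.05,
    expression: ExpressionMatrix | None = None,
    bonferroni_tests: int | None = None,
) -> AssociationResult:
    """Spearman-test every module profile against every trait.

    ``profiles`` is a module x sample DataFrame (or a ModuleSet together
    with its expression matrix).  The per-test threshold is
    alpha / (n_modules x n_traits); ``bonferroni_tests`` overrides the
    denominator when the family is defined externally.  Binary gender is
    tested with the same rank machinery.  Traits and profiles are
    matched on shared samples; a zero-variance trait is an error.
    """
    if isinstance(profiles, ModuleSet):
        if expression is None:
            raise ValueError("passing a ModuleSet requires the expression matrix")
        profiles = module_profiles(profiles, expression)
    shared = [s for s in profiles.columns if s in set(traits.sample_ids)]
    if not shared:
        raise ValueError("profiles and traits share no samples")
    P = profiles[shared]
    T = traits.values.loc[shared]
    trait_names = list(T.columns)
    for name in trait_names:
        col = T[name].dropna()
        if len(col) >= MIN_PAIRS and np.ptp(col.to_numpy()) == 0:
            raise ValueError(f"trait {name!r} has zero variance")

    n_tests = bonferroni_tests or (len(P.index) * len(trait_names))
    thr = alpha / n_tests
    rows = []
    for mod_id in P.index:
        prof = P.loc[mod_id].to_numpy(dtype=float)
        for name in trait_names:
            tv = T[name].to_numpy(dtype=float)
            ok = np.isfinite(prof) & np.isfinite(tv)
            n = int(ok.sum())
            rho, p = spearman_correlation(prof, tv)
            rows.append({"module_id": mod_id, "trait": name, "n": n,
                         "rho": rho, "p": p, "threshold": thr,
                         "significant": bool(p < thr)})
    table = pd.DataFrame(rows, columns=["module_id", "trait", "n", "rho", "p",
                                        "threshold", "significant"])
    return AssociationResult(table=table, profiles=P, alpha=alpha, threshold=thr)


def conditional_reassessment(
    assoc: AssociationResult,
    traits: TraitTable,
    confounder_sets: dict,
    level: float = 0.05,
) -> ConditionalResult:
    """Re-test each significant (module, trait) pair given confounders.

    For every named confounder set, the partial Spearman correlation is
    computed with the tested trait removed from the set if present; a
    (pair, set) combination whose set reduces to the tested trait alone
    is skipped, and if every requested combination degenerates this way
    the call is an error (adjusting a pair for itself).  The verdict is
    ``confounded`` when the partial p >= ``level``, else ``robust``.
    For single-trait sets the reverse direction is also reported: the
    confounder as outcome, adjusted for the originally associated trait.
    """
    sig = assoc.significant_pairs()
    T = traits.values.loc[assoc.profiles.columns]
    rows = []
    skipped = 0
    for _, rec in sig.iterrows():
        mod_id, trait = rec["module_id"], rec["trait"]
        prof = assoc.profiles.loc[mod_id].to_numpy(dtype=float)
        for set_name, confs in confounder_sets.items():
            confs = list(confs)
            used = [c for c in confs if c != trait]
            if not used:
                logger.warning("skipping confounder set %r for trait %r: "
                               "cannot adjust a pair for itself", set_name, trait)
                skipped += 1
                continue
            if len(used) < len(confs):
                logger.warning("dropping tested trait %r from confounder set %r", trait, set_name)
            vecs = [T[c].to_numpy(dtype=float) for c in used]
            prho, pp = partial_spearman(prof, T[trait].to_numpy(dtype=float), vecs)
            rows.append({"module_id": mod_id, "trait": trait,
                         "confounder_set": set_name, "confounders": ",".join(used),
                         "direction": "forward", "partial_rho": prho, "partial_p": pp,
                         "verdict": "confounded" if pp >= level else "robust"})
            if len(used) == 1:
                c = used[0]
                prho_r, pp_r = partial_spearman(
                    prof, T[c].to_numpy(dtype=float), [T[trait].to_numpy(dtype=float)])
                rows.append({"module_id": mod_id, "trait": c,
                             "confounder_set": set_name, "confounders": trait,
                             "direction": "reverse", "partial_rho": prho_r, "partial_p": pp_r,
                             "verdict": "confounded" if pp_r >= level else "robust"})
    if not rows and skipped:
        raise ValueError("every confounder set equals its tested trait; "
                         "nothing can be adjusted")
    table = pd.DataFrame(rows, columns=["module_id", "trait", "confounder_set",
                                        "confounders", "direction",
                                        "partial_rho", "partial_p", "verdict"])
    return ConditionalResult(table=table, level=level)


def flag_trait_correlated_genes(
    module: Module,
    m: ExpressionMatrix,
    trait,
    p_cut: float = 0.01,
    ann=None,
) -> pd.Series:
    """Flag the module members individually correlated with a trait.

    Each member probe is Spearman-tested against the trait and flagged
    when p < ``p_cut``.  With an annotation, flags are collapsed to gene
    level (a gene is flagged if any of its probes is).
    """
    trait = np.asarray(trait, dtype=float)
    flags = {}
    for p in module.member_probe_ids:
        x = m.values.loc[p].to_numpy(dtype=float)
        _rho, pv = spearman_correlation(x, trait)
        flags[p] = bool(pv < p_cut)
    s = pd.Series(flags, name="trait_correlated")
    if ann is None:
        return s
    gene_flags: dict = {}
    for p, f in s.items():
        g = ann.gene(p) or p
        gene_flags[g] = gene_flags.get(g, False) or f
    return pd.Series(gene_flags, name="trait_correlated")


def neglog10_table(assoc: AssociationResult) -> pd.DataFrame:
    """-log10 p per (module, trait) — the data behind per-module
    trait-association profile plots."""
    t = assoc.table.pivot(index="module_id", columns="trait", values="p")
    return -np.log10(t)
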