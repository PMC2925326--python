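"""SAT-vs-VAT per-probe differential expression.

Each probe shared by the two depot matrices is tested with a two-sided
Wilcoxon Mann-Whitney U test (exact enumeration for small groups, else
the tie- and continuity-corrected normal approximation), given a fold
change (ratio of group means of linear intensities, reported >= 1 with a
direction), flagged by Bonferroni-corrected significance, binned by fold
change, and optionally fed to the random stratified selection used to
pick validation candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

UP_IN_SAT = "up_in_SAT"
UP_IN_VAT = "up_in_VAT"


@dataclass
class DEParams:
    alpha: float = 0.05
    fc_thresholds: tuple = (1.5, 10.0)
    exact_test_max_n: int = 8
    fc_estimator: str = "mean"     # or "median"
    fc_tolerance: float = 1e-12    # relative band treated as "no change"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if any(t <= 1.0 for t in self.fc_thresholds):
            raise ValueError("fold-change thresholds must be > 1")
        if self.fc_estimator not in ("mean", "median"):
            raise ValueError(f"unknown fc_estimator {self.fc_estimator!r}")


@dataclass
class DEResult:
    """Per-probe table: p_value, fold_change (>= 1), direction,
    bonferroni_significant; plus the threshold used."""

    table: pd.DataFrame
    params: DEParams
    threshold: float


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise per-test threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def tissue_differential_expression(
    sat: ExpressionMatrix, vat: ExpressionMatrix, params: DEParams | None = None
) -> DEResult:
    """Mann-Whitney SAT-vs-VAT test for every shared probe.

    The exact null distribution is enumerated when both group sizes are
    at most ``exact_test_max_n``; otherwise the normal approximation with
    mid-rank tie correction and continuity correction is used.  The fold
    change is larger/smaller of the two group summaries (means by
    default) of linear-scale intensities.
    """
    params = params or DEParams()
    if sat.shape[1] < 2 or vat.shape[1] < 2:
        raise ValueError("need at least 2 samples per depot")
    shared = [p for p in sat.probe_ids if p in set(vat.probe_ids)]
    if len(shared) < len(sat.probe_ids) or len(shared) < len(vat.probe_ids):
        logger.warning("probe panels differ; testing %d shared probes", len(shared))
    if not shared:
        raise ValueError("no shared probes between depots")
    Xs = sat.values.loc[shared].to_numpy(dtype=float)
    Xv = vat.values.loc[shared].to_numpy(dtype=float)

    n1, n2 = Xs.shape[1], Xv.shape[1]
    method = "exact" if max(n1, n2) <= params.exact_test_max_n else "asymptotic"
    res = stats.mannwhitneyu(Xs, Xv, axis=1, alternative="two-sided", method=method)
    pvals = np.atleast_1d(res.pvalue)

    summarize = np.mean if params.fc_estimator == "mean" else np.median
    ms = summarize(Xs, axis=1)
    mv = summarize(Xv, axis=1)
    hi = np.maximum(ms, mv)
    lo = np.minimum(ms, mv)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lo > 0, hi / lo, np.inf)
    same = np.isclose(ms, mv, rtol=params.fc_tolerance, atol=0.0)
    fc = np.where(same, 1.0, fc)
    direction = np.where(same, "none", np.where(ms > mv, UP_IN_SAT, UP_IN_VAT))

    thr = bonferroni_threshold(params.alpha, len(shared))
    table = pd.DataFrame(
        {
            "p_value": pvals,
            "fold_change": fc,
            "direction": direction,
            "bonferroni_significant": pvals < thr,
        },
        index=pd.Index(shared, name="probe_id"),
    )
    return DEResult(table=table, params=params, threshold=thr)


def fold_change_bins(
    de: DEResult, params: DEParams | None = None, ann: ProbeAnnotation | None = None
) -> pd.DataFrame:
    """Counts of Bonferroni-significant probes (and genes, when an
    annotation is given) exceeding each fold-change threshold per
    direction.  Bins are strict (> threshold)."""
    params = params or de.params
    t = de.table
    sig = t[t["bonferroni_significant"]]
    rows = []
    for direction in (UP_IN_SAT, UP_IN_VAT):
        d = sig[sig["direction"] == direction]
        for thr in params.fc_thresholds:
            sub = d[d["fold_change"] > thr]
            row = {"direction": direction, "fc_threshold": thr, "n_probes": len(sub)}
            if ann is not None:
                row["n_genes"] = len(ann.genes_of(sub.index))
            rows.append(row)
    return pd.DataFrame(rows)


def collapse_to_genes(de: DEResult, ann: ProbeAnnotation) -> pd.DataFrame:
    """Collapse probes to genes keeping each gene's best-p probe.

    Unannotated probes stand for themselves.  Ties on p are broken by
    probe id for determinism.
    """
    t = de.table.reset_index()
    t["gene"] = [ann.gene(p) or p for p in t["probe_id"]]
    t = t.sort_values(["gene", "p_value", "probe_id"], kind="mergesort")
    return t.groupby("gene", sort=True).first()


def stratified_random_selection(
    de: DEResult,
    direction: str,
    n_bins: int = 10,
    seed: int = 0,
    ann: ProbeAnnotation | None = None,
) -> list:
    """Pick one gene per fold-change decile among significant genes.

    Significant genes up in ``direction`` are sorted by fold change
    descending and split into ``n_bins`` contiguous bins as equal as
    possible (the remainder is spread over the first bins); one gene is
    drawn uniformly from each bin.  Reproducible given ``seed``.
    """
    if direction not in (UP_IN_SAT, UP_IN_VAT):
        raise ValueError(f"direction must be {UP_IN_SAT} or {UP_IN_VAT}")
    if ann is not None:
        t = collapse_to_genes(de, ann)
        names = t.index.to_numpy()
    else:
        t = de.table
        names = t.index.to_numpy()
    mask = (t["direction"] == direction) & t["bonferroni_significant"]
    sub = t[mask.to_numpy()]
    names = names[mask.to_numpy()]
    if len(sub) < n_bins:
        raise ValueError(f"only {len(sub)} genes in {direction}; need >= {n_bins}")
    order = np.lexsort((names, -sub["fold_change"].to_numpy()))
    names = names[order]

    n = len(names)
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    rng = np.random.default_rng(seed)
    picks = []
    start = 0
    for size in sizes:
        picks.append(str(names[start + rng.integers(size)]))
        start += size
    return picks


def de_table(de: DEResult, ann: ProbeAnnotation | None = None) -> pd.DataFrame:
    """Flat export: probe_id, gene_symbol, p_value, bonferroni_significant,
    fold_change, direction."""
    t = de.table.reset_index()
    t.insert(1, "gene_symbol", [(ann.gene(p) or "") if ann else "" for p in t["probe_id"]])
    return t[["probe_id", "gene_symbol", "p_value", "bonferroni_significant",
              "fold_change", "direction"]]
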