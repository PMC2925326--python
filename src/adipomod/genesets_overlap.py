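"""Hypergeometric / Fisher's-exact overlap statistics between gene sets.

Given two gene sets drawn from a common universe (20,000 unique genes by
default), the one-sided overrepresentation p-value is the hypergeometric
upper tail P(X >= k), summed exactly in log space so that values far
below the double underflow threshold remain representable.  The same
machinery produces the module-vs-module cross-tabulation of the largest
modules of two depots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .data_io import ProbeAnnotation
from .module_builder import ModuleSet

logger = logging.getLogger(__name__)

DEFAULT_UNIVERSE = 20_000


@dataclass
class GeneSet:
    """A named set of unique, case-normalized gene symbols."""

    name: str
    genes: frozenset

    @classmethod
    def from_symbols(cls, name: str, symbols) -> "GeneSet":
        return cls(name=name, genes=frozenset(str(s).upper() for s in symbols))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OverlapResult:
    """2x2 contingency table and hypergeometric tail for a set overlap."""

    size_a: int
    size_b: int
    overlap: int
    universe: int
    table: list            # [[k, |A|-k], [|B|-k, N-|A|-|B|+k]]
    p: float               # one-sided (overrepresentation) by default
    log10_p: float
    odds_ratio: float
    alternative: str = "greater"


def hypergeom_tail(k: int, size_a: int, size_b: int, universe: int) -> tuple[float, float]:
    """Exact log-space upper tail P(X >= k), X ~ Hypergeom(N, |A|, |B|).

    Returns (p, log10 p); p underflows to 0.0 for extreme tails but
    log10 p never does.
    """
    _check_counts(k, size_a, size_b, universe)
    if k == 0:
        return 1.0, 0.0
    kmax = min(size_a, size_b)
    ks = np.arange(k, kmax + 1)
    logp = hypergeom.logpmf(ks, universe, size_a, size_b)
    log_tail = float(logsumexp(logp))
    log_tail = min(log_tail, 0.0)
    return float(np.exp(log_tail)), log_tail / np.log(10.0)


def _check_counts(k: int, size_a: int, size_b: int, universe: int) -> None:
    if not (0 <= k <= min(size_a, size_b)):
        raise ValueError(f"overlap {k} exceeds a set size ({size_a}, {size_b})")
    if size_a > universe or size_b > universe:
        raise ValueError("set size exceeds universe")
    if universe < size_a + size_b - k:
        raise ValueError("universe smaller than the union of the sets")


def overlap_from_counts(
    k: int, size_a: int, size_b: int,
    universe: int = DEFAULT_UNIVERSE,
    alternative: str = "greater",
) -> OverlapResult:
    """Overlap statistics from the raw counts of a 2x2 table."""
    _check_counts(k, size_a, size_b, universe)
    a = k
    b = size_a - k
    c = size_b - k
    d = universe - size_a - size_b + k
    if alternative == "greater":
        p, log10p = hypergeom_tail(k, size_a, size_b, universe)
    elif alternative == "two-sided":
        from scipy.stats import fisher_exact

        _or, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        log10p = float(np.log10(p)) if p > 0 else -np.inf
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return OverlapResult(size_a=size_a, size_b=size_b, overlap=k, universe=universe,
                         table=[[a, b], [c, d]], p=p, log10_p=log10p,
                         odds_ratio=float(odds), alternative=alternative)


def fisher_overlap(
    a: GeneSet, b: GeneSet,
    universe: int | GeneSet = DEFAULT_UNIVERSE,
    alternative: str = "greater",
) -> OverlapResult:
    """One-sided overrepresentation test for two gene sets.

    ``universe`` is either the number of genes assayed or an explicit
    GeneSet of which both sets must be subsets.
    """
    if isinstance(universe, GeneSet):
        if not (a.genes <= universe.genes and b.genes <= universe.genes):
            raise ValueError("sets are not subsets of the given universe")
        n_universe = len(universe)
    else:
        n_universe = int(universe)
    k = len(a.genes & b.genes)
    return overlap_from_counts(k, len(a), len(b), n_universe, alternative=alternative)


# ---------------------------------------------------------------------------
# Module cross-tabulation
# ---------------------------------------------------------------------------

def module_gene_sets(ms: ModuleSet, ann: ProbeAnnotation) -> list:
    """Collapse each multi-probe module to its distinct-gene set.

    Unannotated probes stand for themselves (they count as distinct
    genes but can only match the identical probe id in another set).
    """
    return [GeneSet.from_symbols(mod.module_id, ann.genes_of(mod.member_probe_ids))
            for mod in ms.multi()]


def module_overlap_table(
    a: ModuleSet, b: ModuleSet, ann: ProbeAnnotation,
    top_k: int = 10, universe: int = DEFAULT_UNIVERSE,
) -> tuple[pd.DataFrame, dict]:
    """Cross-tab of distinct-gene overlaps between the largest modules.

    Rows are the ``top_k`` largest modules of ``a`` and columns those of
    ``b``, ordered by gene count descending (ties broken by module id);
    cells are intersection counts.  Returns the count table (with row
    and column totals) plus a dict of per-cell OverlapResult keyed by
    (row_module, col_module).
    """
    sets_a = module_gene_sets(a, ann)
    sets_b = module_gene_sets(b, ann)
    if top_k > len(sets_a) or top_k > len(sets_b):
        logger.warning("top_k=%d exceeds module count (%d, %d); clamping",
                       top_k, len(sets_a), len(sets_b))
        top_k = min(top_k, len(sets_a), len(sets_b))
    key = lambda g: (-len(g), g.name)
    top_a = sorted(sets_a, key=key)[:top_k]
    top_b = sorted(sets_b, key=key)[:top_k]
    counts = pd.DataFrame(0, index=[g.name for g in top_a],
                          columns=[g.name for g in top_b], dtype=int)
    cells = {}
    for ga in top_a:
        for gb in top_b:
            k = len(ga.genes & gb.genes)
            counts.loc[ga.name, gb.name] = k
            cells[(ga.name, gb.name)] = overlap_from_counts(
                k, len(ga), len(gb), universe)
    counts.insert(0, "total", [len(g) for g in top_a])
    totals = pd.DataFrame([[0] + [len(g) for g in top_b]],
                          index=["total"], columns=counts.columns)
    counts = pd.concat([totals, counts])
    return counts, cells


# ---------------------------------------------------------------------------
# Gene-list I/O
# ---------------------------------------------------------------------------

def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One symbol per line; a ``#`` prefix marks comments."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.append(s)
    from pathlib import Path

    return GeneSet.from_symbols(name or Path(path).stem, symbols)


def read_gene_sets_tsv(path) -> dict:
    """Two-column TSV (set_name, gene) -> {name: GeneSet}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for name, grp in df.groupby(df.columns[0]):
        out[name] = GeneSet.from_symbols(name, grp.iloc[:, 1])
    return out
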