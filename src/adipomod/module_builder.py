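"""Greedy iterative construction of co-expression modules.

The algorithm repeatedly finds the most strongly *positively* correlated
pair among the current items — unmerged probes and previously created
modules — and merges it into a single item whose expression profile is
recomputed as the unweighted mean over all constituent probe rows.  It
stops as soon as the best remaining pair correlates below the threshold
(r < 0.65 by default).  Negative correlations never trigger a merge:
anti-correlated probes may reflect mutually exclusive processes.

Unlike classical hierarchical clustering there is no fixed dendrogram
cut: the stop rule operates on actual profile correlations, and because
averaging denoises, a later merge may exceed an earlier one — merge
correlations are not monotone.

Two execution strategies are provided.  ``naive`` recomputes the full
pairwise correlation table at every iteration (the reference semantics);
``cached`` keeps the table and refreshes only the rows touched by a
merge.  Both share the same correlation kernel, so they produce
bit-identical merge sequences; the cached strategy handles panels of a
few thousand probes in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)


@dataclass
class ModuleBuildParams:
    """Knobs of the greedy merger.

    r_stop : merge threshold; iteration stops when the best positive
        pairwise correlation drops below it (default 0.65).
    min_genes : distinct-gene size filter applied downstream (default 5).
    profile_rule : ``probe_mean`` recomputes the profile as the mean over
        all constituent probe rows (default); ``pair_mean`` averages the
        two merged profiles (WPGMA-like), which differs for unequal sizes.
    tie_break : among pairs attaining the maximum r, take the one with the
        lexicographically smallest (older creation index, newer creation
        index); the only rule provided, it makes runs deterministic and
        strategy-comparable.
    """

    r_stop: float = 0.65
    min_genes: int = 5
    profile_rule: str = "probe_mean"
    tie_break: str = "creation_order"

    def __post_init__(self) -> None:
        if not 0.0 < self.r_stop < 1.0:
            raise ValueError("r_stop must be in (0, 1)")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if self.profile_rule not in ("probe_mean", "pair_mean"):
            raise ValueError(f"unknown profile_rule {self.profile_rule!r}")
        if self.tie_break != "creation_order":
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class Module:
    """One final item: a probe group with its profile and merge history.

    ``member_probe_ids`` are listed in merge order (the order used for
    heatmap display); ``merge_history`` records (left_id, right_id, r)
    for every merge that formed this item, chronologically.
    """

    module_id: str
    member_probe_ids: list
    profile: np.ndarray
    merge_history: list = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.member_probe_ids)


@dataclass
class ModuleSet:
    """All final items (multi-probe modules and leftover singletons)."""

    modules: list
    params: ModuleBuildParams
    probe_universe: list
    sample_ids: list
    #: global merge log: (step, left_id, right_id, r, new_id)
    history: list = field(default_factory=list)

    def multi(self) -> list:
        return [m for m in self.modules if m.n_probes > 1]

    def __iter__(self):
        return iter(self.modules)


# ---------------------------------------------------------------------------
# Correlation kernels (shared by both build strategies)
# ---------------------------------------------------------------------------

def _standardize(profile: np.ndarray) -> np.ndarray:
    """Center and L2-normalize so that dot products are Pearson r.
    A (near-)constant profile maps to zeros: its correlations read as 0."""
    c = profile - profile.mean()
    nrm = np.sqrt((c * c).sum())
    if nrm < 1e-12:
        return np.zeros_like(c)
    return c / nrm


def _corr_row(z: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Pearson r of one standardized profile against a stack of them.

    Computed as one scalar dot product per pair rather than a single
    matrix-vector product: BLAS gemv accumulation can differ in the last
    ulp depending on the stack shape, and the two build strategies must
    agree bit-for-bit on every correlation they both evaluate.
    """
    return np.fromiter((z @ row for row in Z), dtype=float, count=len(Z))


def pairwise_pearson(m: ExpressionMatrix) -> pd.DataFrame:
    """Full symmetric probe x probe Pearson correlation table.

    Zero-variance probes are excluded (with a warning) since their
    correlation is undefined.  Requires at least 3 samples.
    """
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples for pairwise correlation")
    X = m.values.to_numpy(dtype=float)
    var = X.var(axis=1)
    keep = var > 0.0
    if not keep.all():
        dropped = [p for p, k in zip(m.probe_ids, keep) if not k]
        logger.warning("excluding %d zero-variance probes: %s", len(dropped), dropped[:5])
    ids = [p for p, k in zip(m.probe_ids, keep) if k]
    Z = np.vstack([_standardize(row) for row in X[keep]])
    R = Z @ Z.T
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# The greedy merger
# ---------------------------------------------------------------------------

class _Item:
    __slots__ = ("item_id", "creation_index", "members", "member_rows", "profile", "z")

    def __init__(self, item_id, creation_index, members, member_rows, profile):
        self.item_id = item_id
        self.creation_index = creation_index
        self.members = members          # probe ids in merge order
        self.member_rows = member_rows  # row indices into the expression matrix
        self.profile = profile
        self.z = _standardize(profile)


class _BuildState:
    """Shared bookkeeping: items, creation counter, global merge log."""

    def __init__(self, X: np.ndarray, params: ModuleBuildParams):
        self.X = X
        self.params = params
        self.next_creation = 0
        self.next_module_number = 1
        self.history: list[tuple] = []

    def new_probe_item(self, probe_id, row_index) -> _Item:
        it = _Item(probe_id, self.next_creation, [probe_id],
                   np.array([row_index]), self.X[row_index].astype(float))
        self.next_creation += 1
        return it

    def merge(self, a: _Item, b: _Item, r: float) -> _Item:
        left, right = (a, b) if a.creation_index < b.creation_index else (b, a)
        new_id = f"M{self.next_module_number}"
        self.next_module_number += 1
        if self.params.profile_rule == "probe_mean":
            rows = np.sort(np.concatenate([left.member_rows, right.member_rows]))
            profile = self.X[rows].mean(axis=0)
        else:
            profile = 0.5 * (left.profile + right.profile)
        it = _Item(new_id, self.next_creation,
                   list(left.members) + list(right.members),
                   np.concatenate([left.member_rows, right.member_rows]),
                   profile)
        self.next_creation += 1
        self.history.append((len(self.history) + 1, left.item_id, right.item_id,
                             float(r), new_id))
        return it


def _pick_pair(cands, items_by_pos) -> tuple[int, int]:
    """Deterministic tie-break: smallest (older, newer) creation-index pair."""
    best_key, best_pos = None, None
    for i, j in cands:
        a, b = items_by_pos[i], items_by_pos[j]
        key = (min(a.creation_index, b.creation_index),
               max(a.creation_index, b.creation_index))
        if best_key is None or key < best_key:
            best_key, best_pos = key, (i, j)
    return best_pos


def build_modules(
    m: ExpressionMatrix,
    params: ModuleBuildParams | None = None,
    method: str = "cached",
) -> ModuleSet:
    """Run the greedy iterative merger on a normalized expression matrix.

    Returns every final item — multi-probe modules and remaining
    singleton probes — each with its full merge history.  ``method``
    selects the ``cached`` table-update strategy or the ``naive``
    full-recompute reference; their outputs are identical.
    """
    params = params or ModuleBuildParams()
    if method not in ("cached", "naive"):
        raise ValueError(f"unknown method {method!r}")
    if m.shape[0] == 0:
        raise ValueError("empty expression matrix")
    X = m.values.to_numpy(dtype=float)
    probe_ids = m.probe_ids

    var = X.var(axis=1)
    excluded = {p for p, v in zip(probe_ids, var) if v <= 0.0}
    if excluded:
        logger.warning("excluding %d zero-variance probes from clustering", len(excluded))

    state = _BuildState(X, params)
    items = [state.new_probe_item(p, i)
             for i, p in enumerate(probe_ids) if p not in excluded]

    if method == "cached":
        final_items = _run_cached(items, state)
    else:
        final_items = _run_naive(items, state)

    final_items.sort(key=lambda it: it.creation_index)
    histories: dict[str, list] = {}
    for _step, left_id, right_id, r, new_id in state.history:
        h = histories.get(left_id, []) + histories.get(right_id, [])
        h.append((left_id, right_id, r))
        histories[new_id] = h
    modules = [Module(module_id=it.item_id,
                      member_probe_ids=list(it.members),
                      profile=it.profile,
                      merge_history=histories.get(it.item_id, []))
               for it in final_items]
    return ModuleSet(modules=modules, params=params,
                     probe_universe=[p for p in probe_ids if p not in excluded],
                     sample_ids=m.sample_ids,
                     history=list(state.history))


def _run_cached(items: list, state: _BuildState) -> list:
    n0 = len(items)
    if n0 < 2:
        return items
    cap = 2 * n0
    nsamp = items[0].z.shape[0]
    R = np.full((cap, cap), -np.inf)
    Zs = np.zeros((cap, nsamp))
    active = np.zeros(cap, dtype=bool)
    slot_item: list = [None] * cap
    for i, it in enumerate(items):
        Zs[i] = it.z
        if i:
            vals = _corr_row(it.z, Zs[:i])
            R[i, :i] = vals
            R[:i, i] = vals
        active[i] = True
        slot_item[i] = it
    n_slots = n0
    r_stop = state.params.r_stop

    while active.sum() >= 2:
        sub = R[:n_slots, :n_slots]
        best = sub.max()
        if not np.isfinite(best) or best < r_stop:
            break
        cands = [(i, j) for i, j in np.argwhere(sub == best)
                 if i < j and active[i] and active[j]]
        i, j = _pick_pair(cands, slot_item)
        new_item = state.merge(slot_item[i], slot_item[j], best)
        for s in (i, j):
            active[s] = False
            slot_item[s] = None
            R[s, :n_slots] = -np.inf
            R[:n_slots, s] = -np.inf
        s = n_slots
        n_slots += 1
        Zs[s] = new_item.z
        act = np.flatnonzero(active[:s])
        if act.size:
            vals = _corr_row(new_item.z, Zs[act])
            R[s, act] = vals
            R[act, s] = vals
        active[s] = True
        slot_item[s] = new_item
    return [slot_item[s] for s in np.flatnonzero(active[:n_slots])]


def _run_naive(items: list, state: _BuildState) -> list:
    live = list(items)
    r_stop = state.params.r_stop
    while len(live) >= 2:
        Z = np.vstack([it.z for it in live])
        best = -np.inf
        cands: list[tuple[int, int]] = []
        for i in range(1, len(live)):
            row = _corr_row(live[i].z, Z[:i])
            rmax = row.max()
            if rmax > best:
                best = rmax
                cands = [(j, i) for j in np.flatnonzero(row == rmax)]
            elif rmax == best and np.isfinite(best):
                cands.extend((j, i) for j in np.flatnonzero(row == rmax))
        if not np.isfinite(best) or best < r_stop:
            break
        i, j = _pick_pair(cands, live)
        new_item = state.merge(live[i], live[j], best)
        live = [it for t, it in enumerate(live) if t not in (i, j)]
        live.append(new_item)
    return live


# ---------------------------------------------------------------------------
# Profiles and filtering
# ---------------------------------------------------------------------------

def module_profile(module: Module, m: ExpressionMatrix) -> np.ndarray:
    """Unweighted per-sample mean over the module's member probe rows."""
    pos = m.values.index.get_indexer(module.member_probe_ids)
    if (pos < 0).any():
        missing = [p for p, q in zip(module.member_probe_ids, pos) if q < 0]
        raise KeyError(f"member probes missing from matrix: {missing[:5]}")
    return m.values.to_numpy(dtype=float)[np.sort(pos)].mean(axis=0)


def module_profiles(ms: ModuleSet, m: ExpressionMatrix, multi_only: bool = True) -> pd.DataFrame:
    """Profiles of the module set as a module x sample DataFrame."""
    mods = ms.multi() if multi_only else ms.modules
    data = {mod.module_id: module_profile(mod, m) for mod in mods}
    return pd.DataFrame(data, index=m.sample_ids).T


def filter_modules_by_gene_count(
    ms: ModuleSet, ann: ProbeAnnotation, min_genes: int | None = None
) -> ModuleSet:
    """Keep modules whose distinct gene-symbol count reaches ``min_genes``.

    Unannotated probes each count as a distinct gene.
    """
    if min_genes is None:
        min_genes = ms.params.min_genes
    kept = [mod for mod in ms.modules if len(ann.genes_of(mod.member_probe_ids)) >= min_genes]
    return ModuleSet(modules=kept, params=ms.params,
                     probe_universe=ms.probe_universe, sample_ids=ms.sample_ids,
                     history=ms.history)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def module_table(ms: ModuleSet, ann: ProbeAnnotation | None = None) -> pd.DataFrame:
    """One row per (module, probe): module_id, n_probes, n_genes, probe_id, gene_symbol."""
    rows = []
    for mod in ms.modules:
        genes = ann.genes_of(mod.member_probe_ids) if ann else set(mod.member_probe_ids)
        for p in mod.member_probe_ids:
            rows.append({
                "module_id": mod.module_id,
                "n_probes": mod.n_probes,
                "n_genes": len(genes),
                "probe_id": p,
                "gene_symbol": (ann.gene(p) or "") if ann else "",
            })
    return pd.DataFrame(rows, columns=["module_id", "n_probes", "n_genes", "probe_id", "gene_symbol"])


def merge_history_table(ms: ModuleSet) -> pd.DataFrame:
    """Chronological merge log: step, left_id, right_id, r."""
    rows = [{"step": step, "left_id": a, "right_id": b, "r": r}
            for step, a, b, r, _new in ms.history]
    return pd.DataFrame(rows, columns=["step", "left_id", "right_id", "r"])
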