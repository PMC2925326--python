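"""Network/heatmap exports and the end-to-end pipeline.

The exports back the standard presentations of a module analysis: a
within-module co-expression graph connecting probe pairs with r above a
cutoff (0.65, matching the module-building stop rule), and a pairwise
correlation matrix ordered with the largest module in the upper-left
corner for heatmap rendering.  ``run_pipeline`` chains every stage —
simulate (or read) → normalize → QC → differential expression → module
construction → trait association → conditional re-analysis → overlap
cross-tab → exports — writing TSV artifacts plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import data_io, diffexpr, genesets_overlap, module_builder, synthetic, trait_assoc
from .data_io import ExpressionMatrix, QCParams
from .module_builder import Module, ModuleBuildParams, ModuleSet

logger = logging.getLogger(__name__)


@dataclass
class EdgeList:
    """Within-module co-expression edges above a correlation cutoff."""

    module_id: str
    edges: list            # (probe_a, probe_b, r)
    isolated: list         # members with no edge above r_min
    r_min: float


def coexpression_edges(module: Module, m: ExpressionMatrix, r_min: float = 0.65) -> EdgeList:
    """All within-module probe pairs with pairwise Pearson r > r_min
    (strict).  Members without any such edge are listed separately, as
    they are omitted from the drawn graph."""
    members = module.member_probe_ids
    sub = ExpressionMatrix(values=m.values.loc[members], tissue=m.tissue,
                           normalized=m.normalized)
    edges = []
    connected = set()
    if len(members) >= 2 and sub.shape[1] >= 3:
        R = module_builder.pairwise_pearson(sub)
        ids = list(R.index)
        arr = R.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if arr[i, j] > r_min:
                    edges.append((ids[i], ids[j], float(arr[i, j])))
                    connected.add(ids[i])
                    connected.add(ids[j])
    isolated = [p for p in members if p not in connected]
    return EdgeList(module_id=module.module_id, edges=edges,
                    isolated=isolated, r_min=r_min)


def edges_to_graph(edge_list: EdgeList, ann=None, trait_flags: pd.Series | None = None) -> nx.Graph:
    """NetworkX graph of an edge list; node attributes carry the gene
    symbol and the per-gene trait-correlation flag used for coloring."""
    g = nx.Graph(module_id=edge_list.module_id, r_min=edge_list.r_min)
    for a, b, r in edge_list.edges:
        g.add_edge(a, b, r=r)
    for n in g.nodes:
        gene = (ann.gene(n) or n) if ann else n
        g.nodes[n]["gene_symbol"] = gene
        if trait_flags is not None:
            flag = trait_flags.get(n, trait_flags.get(gene, False))
            g.nodes[n]["trait_correlated"] = bool(flag)
    return g


def write_edge_list(edge_list: EdgeList, path) -> None:
    df = pd.DataFrame(edge_list.edges, columns=["probe_a", "probe_b", "r"])
    df.insert(0, "module_id", edge_list.module_id)
    df.to_csv(path, sep="\t", index=False)


def heatmap_matrix(ms: ModuleSet, m: ExpressionMatrix):
    """Probe ordering, full correlation matrix, and module boundaries.

    Probes are ordered by module size descending (probe count; ties by
    module id), with merge order inside each module; boundaries are the
    cumulative probe counts marking module extents.  The matrix is
    symmetric with unit diagonal.
    """
    mods = sorted(ms.modules, key=lambda mod: (-mod.n_probes, mod.module_id))
    order = [p for mod in mods for p in mod.member_probe_ids]
    sub = ExpressionMatrix(values=m.values.loc[order], tissue=m.tissue,
                           normalized=m.normalized)
    R = module_builder.pairwise_pearson(sub)
    boundaries = list(np.cumsum([mod.n_probes for mod in mods]))
    return order, R, boundaries


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the CLI flags.

    Either ``synthetic=True`` (the default cohort design, or the design
    YAML named by ``design_path``) or explicit input paths for the two
    expression matrices, trait table, and probe annotation.
    """

    outdir: str = "adipomod_out"
    seed: int = 0
    synthetic: bool = True
    design_path: str | None = None
    sat_path: str | None = None
    vat_path: str | None = None
    traits_path: str | None = None
    annotation_path: str | None = None
    expression_format: str = "tsv"
    qc: dict = field(default_factory=dict)
    build: dict = field(default_factory=dict)
    alpha: float = 0.05
    confounder_traits: list = field(default_factory=lambda: ["BMI", "insulin", "glucose"])
    universe: int = genesets_overlap.DEFAULT_UNIVERSE
    top_k: int = 10
    r_min_edges: float = 0.65
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("sat_path", "vat_path", "traits_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config field {name} is required for file input")
                if not Path(p).exists():
                    raise ValueError(f"config field {name}: no such file {p!r}")
        if self.design_path and not Path(self.design_path).exists():
            raise ValueError(f"config field design_path: no such file {self.design_path!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Idempotent: identical config and seed produce identical outputs.
    Any stage failure is re-raised annotated with the stage name.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": asdict(config),
        "versions": _versions(),
        "inputs": {},
        "stages": [],
    }

    stage = "input"
    try:
        if config.synthetic:
            design = (synthetic.design_from_yaml(config.design_path)
                      if config.design_path else synthetic.SyntheticDesign())
            cohort = synthetic.generate_cohort(design, seed=config.seed)
            sat, vat, traits, ann = cohort.sat, cohort.vat, cohort.traits, cohort.annotation
            synthetic.write_truth(cohort, out / "truth.tsv")
            cohort.trait_links.to_csv(out / "trait_links.tsv", sep="\t", index=False)
        else:
            sat = data_io.read_expression_matrix(config.sat_path, config.expression_format, "SAT")
            vat = data_io.read_expression_matrix(config.vat_path, config.expression_format, "VAT")
            traits = data_io.read_trait_table(config.traits_path)
            ann = (data_io.read_probe_annotation(config.annotation_path)
                   if config.annotation_path
                   else data_io.ProbeAnnotation(mapping={}))
            for name in ("sat_path", "vat_path", "traits_path", "annotation_path"):
                p = getattr(config, name)
                if p:
                    manifest["inputs"][name] = _sha256(p)
        manifest["stages"].append(stage)

        stage = "normalize"
        sat_n = data_io.quantile_normalize(sat)
        vat_n = data_io.quantile_normalize(vat)
        manifest["stages"].append(stage)

        stage = "qc"
        qc_params = QCParams(**config.qc)
        results = {}
        for label, mat in (("SAT", sat_n), ("VAT", vat_n)):
            mat_qc, report = data_io.sample_qc(mat, qc_params)
            report.metrics.to_csv(out / f"qc_metrics_{label}.tsv", sep="\t")
            results[label] = mat_qc
        sat_n, vat_n = results["SAT"], results["VAT"]
        manifest["stages"].append(stage)

        stage = "diffexpr"
        de = diffexpr.tissue_differential_expression(sat_n, vat_n)
        diffexpr.de_table(de, ann).to_csv(out / "differential_expression.tsv",
                                          sep="\t", index=False)
        diffexpr.fold_change_bins(de, ann=ann).to_csv(out / "fold_change_bins.tsv",
                                                      sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "build-modules"
        build_params = ModuleBuildParams(**config.build)
        filtered = {}
        module_sets = {}
        for label, mat in (("SAT", sat_n), ("VAT", vat_n)):
            ms = module_builder.build_modules(mat, build_params)
            module_sets[label] = ms
            kept = module_builder.filter_modules_by_gene_count(ms, ann)
            filtered[label] = kept
            module_builder.module_table(kept, ann).to_csv(
                out / f"modules_{label}.tsv", sep="\t", index=False)
            module_builder.merge_history_table(ms).to_csv(
                out / f"merge_history_{label}.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "associate"
        assoc = {}
        for label, mat in (("SAT", sat_n), ("VAT", vat_n)):
            if not filtered[label].multi():
                logger.warning("%s: no modules pass the gene filter; skipping association", label)
                continue
            a = trait_assoc.associate_modules(filtered[label], traits,
                                              alpha=config.alpha, expression=mat)
            assoc[label] = a
            a.table.to_csv(out / f"associations_{label}.tsv", sep="\t", index=False)
            trait_assoc.neglog10_table(a).to_csv(out / f"assoc_neglog10_{label}.tsv", sep="\t")
        manifest["stages"].append(stage)

        stage = "conditional"
        for label, a in assoc.items():
            sets = {c: [c] for c in config.confounder_traits}
            cond = trait_assoc.conditional_reassessment(a, traits, sets)
            cond.table.to_csv(out / f"conditional_{label}.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "overlap"
        if filtered["SAT"].multi() and filtered["VAT"].multi():
            counts, _cells = genesets_overlap.module_overlap_table(
                filtered["SAT"], filtered["VAT"], ann,
                top_k=config.top_k, universe=config.universe)
            counts.to_csv(out / "module_overlap_SAT_vs_VAT.tsv", sep="\t")
        manifest["stages"].append(stage)

        stage = "export-network"
        for label, mat in (("SAT", sat_n), ("VAT", vat_n)):
            a = assoc.get(label)
            if a is None:
                continue
            sig = a.significant_pairs()
            ms = filtered[label]
            by_id = {mod.module_id: mod for mod in ms.modules}
            for mod_id in sig["module_id"].unique():
                mod = by_id[mod_id]
                el = coexpression_edges(mod, mat, config.r_min_edges)
                write_edge_list(el, out / f"edges_{label}_{mod_id}.tsv")
                trait = sig[sig["module_id"] == mod_id]["trait"].iloc[0]
                flags = trait_assoc.flag_trait_correlated_genes(
                    mod, mat, traits.values.loc[mat.sample_ids, trait], ann=ann)
                g = edges_to_graph(el, ann=ann, trait_flags=flags)
                nx.write_graphml(g, out / f"network_{label}_{mod_id}.graphml")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete; artifacts in %s", out)
    return out


def _versions() -> dict:
    import importlib.metadata as md

    out = {}
    for pkg in ("adipomod", "numpy", "scipy", "pandas", "networkx"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out
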