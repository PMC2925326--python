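"""Synthetic two-depot cohort generator with planted ground truth.

The generator emulates the statistical structure of a bulk adipose-tissue
microarray study: ~70 subjects sampled in two fat depots (SAT and VAT),
a panel of hundreds of probes, groups of co-expressed probes driven by a
shared latent factor, clinical traits coupled to those factors, correlated
confounder traits, and depot-specific multiplicative expression shifts.

Model per sample i and probe j in module m:

    x_ij = mu_j + a * f_mi + eps_ij,    f_mi ~ N(0, 1), eps_ij ~ N(0, sigma^2)

with a probe-specific baseline mu_j ~ Uniform(base - w, base + w) emulating
the wide dynamic range of probe intensities on a real array (baselines shift
no correlation, but they are what make inter-sample correlations high, as on
real chips, and give quantile normalization a realistic target; the uniform
law keeps baseline spacings small relative to the noise, so no probe holds a
constant rank — a degenerate state a full-size array never shows but a
normal-tailed baseline would create on a scaled-down panel).  The population
within-module Pearson correlation is a^2 / (a^2 + sigma^2).
A trait linked to module m with effect b is  t_i = b * f_mi + eta_i with
eta_i ~ N(0, trait_noise_sd^2).  Background probes are pure noise; probes
in a tissue-shift group are multiplied by their fold change in the
designated depot.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data_io import DEFAULT_TRAITS, ExpressionMatrix, ProbeAnnotation, TraitTable


@dataclass
class ModuleSpec:
    """A planted co-expression module.

    ``loading`` is the per-probe coefficient on the module's latent factor
    (population within-module r = loading^2 / (loading^2 + noise_sd^2));
    ``trait_links`` couples named traits to the factor with effect size b;
    ``tissue`` is ``SAT``, ``VAT`` or ``both``.
    """

    n_probes: int
    loading: float
    trait_links: list = field(default_factory=list)
    tissue: str = "both"

    def __post_init__(self) -> None:
        if self.n_probes < 2:
            raise ValueError("a module needs at least 2 probes")
        if not 0.0 < abs(self.loading) <= 1.0:
            raise ValueError("|loading| must be in (0, 1]")
        if self.tissue not in ("SAT", "VAT", "both"):
            raise ValueError(f"bad tissue {self.tissue!r}")


@dataclass
class TissueShiftSpec:
    """A block of probes differentially expressed between depots."""

    n_probes: int
    fold_change: float
    up_in: str  # SAT or VAT

    def __post_init__(self) -> None:
        if self.fold_change <= 1.0:
            raise ValueError("fold_change must be > 1")
        if self.up_in not in ("SAT", "VAT"):
            raise ValueError(f"bad depot {self.up_in!r}")


@dataclass
class ConfounderSpec:
    """A pair of traits sharing a Gaussian component with given correlation."""

    trait_a: str
    trait_b: str
    correlation: float

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("correlation must be in (-1, 1)")


@dataclass
class SyntheticDesign:
    """Full specification of a synthetic two-depot cohort.

    Defaults reflect the study conditions this package emulates: 70
    samples per depot, a scaled-down panel of a few hundred probes,
    planted modules with within-module r ~ 0.8, trait couplings giving a
    population module-trait Spearman rho ~ 0.6, correlated metabolic
    confounders, and 1.5-fold / 10-fold tissue-shift classes.
    """

    n_samples: int = 70
    n_background_probes: int = 400
    modules: list = field(default_factory=lambda: [
        ModuleSpec(40, 0.9, trait_links=[("HDL_cholesterol", -0.8)]),
        ModuleSpec(15, 0.9, trait_links=[("glucose", 0.8)]),
        ModuleSpec(8, 0.9),
    ])
    noise_sd: float = 0.43
    tissue_shifts: list = field(default_factory=lambda: [
        TissueShiftSpec(30, 1.8, "VAT"),
        TissueShiftSpec(8, 12.0, "VAT"),
        TissueShiftSpec(20, 1.8, "SAT"),
        TissueShiftSpec(3, 12.0, "SAT"),
    ])
    trait_noise_sd: float = 1.0
    confounders: list = field(default_factory=lambda: [
        ConfounderSpec("glucose", "TG", 0.5),
        ConfounderSpec("glucose", "HbA1c", 0.6),
        ConfounderSpec("BMI", "insulin", 0.5),
    ])
    trait_names: tuple = DEFAULT_TRAITS
    trait_missing_rate: float = 0.02
    base_intensity: float = 10.0
    base_intensity_spread: float = 4.0
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.noise_sd <= 0 or self.trait_noise_sd <= 0:
            raise ValueError("noise sds must be positive")
        seen: set[str] = set()
        for ms in self.modules:
            for name, _b in ms.trait_links:
                if name in seen:
                    raise ValueError(f"trait {name!r} linked to more than one module")
                if name not in self.trait_names:
                    raise ValueError(f"unknown linked trait {name!r}")
                seen.add(name)


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth behind it."""

    sat: ExpressionMatrix
    vat: ExpressionMatrix
    traits: TraitTable
    annotation: ProbeAnnotation
    truth: pd.DataFrame          # probe_id, module_id, tissue_fc, fc_up_in
    trait_links: pd.DataFrame    # module_id, trait, effect


def expected_within_module_correlation(loading: float, noise_sd: float) -> float:
    """Population Pearson correlation between two probes of one module,
    a^2 / (a^2 + sigma^2)."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    a2 = loading * loading
    return a2 / (a2 + noise_sd * noise_sd)


def generate_cohort(design: SyntheticDesign, seed: int | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``design``.

    Module factors are shared between depots (the same subjects carry the
    same latent biology in both), while measurement noise is independent
    per depot.  The returned truth table partitions every probe into its
    module (or ``background`` / shift-group label).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    probe_ids: list[str] = []
    rows_sat: list[np.ndarray] = []
    rows_vat: list[np.ndarray] = []
    truth_module: list[str] = []
    truth_fc: list[float] = []
    truth_fc_dir: list[str] = []
    link_rows = []

    factors = rng.standard_normal((len(design.modules), n))
    for k, ms in enumerate(design.modules):
        mod_id = f"PM{k + 1}"
        f = factors[k]
        for j in range(ms.n_probes):
            probe_ids.append(f"{mod_id}_P{j + 1:03d}")
            truth_module.append(mod_id)
            truth_fc.append(1.0)
            truth_fc_dir.append("none")
            mu = design.base_intensity + design.base_intensity_spread * rng.uniform(-1.0, 1.0)
            for depot, rows in (("SAT", rows_sat), ("VAT", rows_vat)):
                if ms.tissue in (depot, "both"):
                    x = mu + ms.loading * f + design.noise_sd * rng.standard_normal(n)
                else:
                    x = mu + design.noise_sd * rng.standard_normal(n)
                rows.append(x)
        for trait, b in ms.trait_links:
            link_rows.append({"module_id": mod_id, "trait": trait, "effect": b})

    for s, spec in enumerate(design.tissue_shifts):
        for j in range(spec.n_probes):
            probe_ids.append(f"FC{s + 1}_{spec.up_in}_P{j + 1:03d}")
            truth_module.append("background")
            truth_fc.append(spec.fold_change)
            truth_fc_dir.append(spec.up_in)
            mu = design.base_intensity + design.base_intensity_spread * rng.uniform(-1.0, 1.0)
            xs = mu + design.noise_sd * rng.standard_normal(n)
            xv = mu + design.noise_sd * rng.standard_normal(n)
            if spec.up_in == "SAT":
                xs = xs * spec.fold_change
            else:
                xv = xv * spec.fold_change
            rows_sat.append(xs)
            rows_vat.append(xv)

    for j in range(design.n_background_probes):
        probe_ids.append(f"BG_P{j + 1:04d}")
        truth_module.append("background")
        truth_fc.append(1.0)
        truth_fc_dir.append("none")
        mu = design.base_intensity + design.base_intensity_spread * rng.uniform(-1.0, 1.0)
        rows_sat.append(mu + design.noise_sd * rng.standard_normal(n))
        rows_vat.append(mu + design.noise_sd * rng.standard_normal(n))

    sat = ExpressionMatrix(
        values=pd.DataFrame(np.vstack(rows_sat), index=probe_ids, columns=sample_ids),
        tissue="SAT",
    )
    vat = ExpressionMatrix(
        values=pd.DataFrame(np.vstack(rows_vat), index=probe_ids, columns=sample_ids),
        tissue="VAT",
    )

    # Traits: linked traits ride on their module factor; confounded pairs
    # share a Gaussian component; everything else is independent noise.
    linked = {r["trait"]: (r["module_id"], r["effect"]) for r in link_rows}
    module_index = {f"PM{k + 1}": k for k in range(len(design.modules))}
    traits = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"), dtype=float)
    for name in design.trait_names:
        if name == "gender":
            traits[name] = rng.integers(0, 2, size=n).astype(float)
        elif name in linked:
            mod_id, b = linked[name]
            f = factors[module_index[mod_id]]
            traits[name] = b * f + design.trait_noise_sd * rng.standard_normal(n)
        else:
            traits[name] = design.trait_noise_sd * rng.standard_normal(n)
    for conf in design.confounders:
        # add a shared component to induce the requested correlation while
        # leaving any factor-driven signal in place
        if conf.trait_a not in traits or conf.trait_b not in traits:
            raise ValueError(f"confounder names unknown trait: {conf}")
        shared = rng.standard_normal(n)
        rho = conf.correlation
        w = np.sqrt(abs(rho) / (1 - abs(rho)))
        sa = traits[conf.trait_a].to_numpy()
        sb = traits[conf.trait_b].to_numpy()
        sa = sa + w * design.trait_noise_sd * shared
        sb = sb + np.sign(rho) * w * design.trait_noise_sd * shared
        traits[conf.trait_a] = sa
        traits[conf.trait_b] = sb
    if design.trait_missing_rate > 0:
        for name in design.trait_names:
            if name == "gender":
                continue
            mask = rng.random(n) < design.trait_missing_rate
            traits.loc[mask, name] = np.nan

    mapping = {}
    for idx, p in enumerate(probe_ids):
        gene_idx = idx // max(design.probes_per_gene, 1)
        mapping[p] = f"GENE{gene_idx + 1:05d}"
    ann = ProbeAnnotation(mapping=mapping)

    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "module_id": truth_module,
            "tissue_fc": truth_fc,
            "fc_up_in": truth_fc_dir,
        }
    )
    return SyntheticCohort(
        sat=sat,
        vat=vat,
        traits=TraitTable(values=traits),
        annotation=ann,
        truth=truth,
        trait_links=pd.DataFrame(link_rows, columns=["module_id", "trait", "effect"]),
    )


# ---------------------------------------------------------------------------
# Design (de)serialization — plain YAML mapping
# ---------------------------------------------------------------------------

def design_to_yaml(design: SyntheticDesign, path) -> None:
    doc = asdict(design)
    doc["modules"] = [asdict(m) for m in design.modules]
    doc["tissue_shifts"] = [asdict(s) for s in design.tissue_shifts]
    doc["confounders"] = [asdict(c) for c in design.confounders]
    doc["trait_names"] = list(design.trait_names)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def design_from_yaml(path) -> SyntheticDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc["modules"] = [ModuleSpec(**{**m, "trait_links": [tuple(t) for t in m.get("trait_links", [])]})
                      for m in doc.get("modules", [])]
    doc["tissue_shifts"] = [TissueShiftSpec(**s) for s in doc.get("tissue_shifts", [])]
    doc["confounders"] = [ConfounderSpec(**c) for c in doc.get("confounders", [])]
    if "trait_names" in doc:
        doc["trait_names"] = tuple(doc["trait_names"])
    return SyntheticDesign(**doc)


def write_truth(cohort: SyntheticCohort, path) -> None:
    cohort.truth.to_csv(path, sep="\t", index=False)
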