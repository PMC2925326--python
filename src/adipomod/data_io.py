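"""Tabular I/O, quantile normalization, and sample quality control.

Expression data are probe x sample matrices of non-negative fluorescence
intensities, one matrix per adipose depot (SAT = subcutaneous, VAT =
visceral).  Clinical traits live in a per-sample table that may contain
missing values.  Normalization forces every sample onto the mean
order-statistic reference ("quantile-quantile" normalization, applied per
tissue); QC screens samples on median intensity, mean inter-sample
correlation, principal components, and optionally the behaviour of known
housekeeping probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("SAT", "VAT", "OTHER")

#: Canonical clinical traits measured in the cohort (gender is 0/1 coded).
DEFAULT_TRAITS = (
    "gender", "age", "BMI", "glucose", "insulin", "HbA1c",
    "total_cholesterol", "HDL_cholesterol", "LDL_cholesterol",
    "TG", "NEFA", "ALAT", "ASAT", "CRP",
)


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with a tissue label.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe id, columns by sample id; dense, finite,
        non-negative intensities in arbitrary fluorescence units.
    tissue : str
        One of ``SAT``, ``VAT`` or ``OTHER``.
    normalized : bool
        Whether :func:`quantile_normalize` has been applied.
    """

    values: pd.DataFrame
    tissue: str = "OTHER"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ParseError(f"duplicate probe id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite value at probe {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbeAnnotation:
    """Mapping probe id -> gene symbol; probes may lack a symbol."""

    mapping: dict

    def gene(self, probe_id) -> str | None:
        return self.mapping.get(probe_id)

    def genes_of(self, probe_ids: Sequence) -> set:
        """Distinct gene identities for a probe collection.

        Unannotated probes each count as their own distinct gene (they
        cannot be collapsed), represented by the probe id itself.
        """
        out = set()
        for p in probe_ids:
            g = self.mapping.get(p)
            out.add(g if g else p)
        return out


@dataclass
class TraitTable:
    """Per-sample clinical trait values; missing entries allowed.

    ``values`` is indexed by sample id with one numeric column per trait.
    Gender, when present, is 0/1 coded (NaN = missing).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        if "gender" in self.values.columns:
            g = self.values["gender"].dropna()
            if not g.isin([0, 1]).all():
                raise ParseError("gender values must be 0/1 or missing")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def trait_names(self) -> list:
        return list(self.values.columns)

    def trait(self, name: str) -> pd.Series:
        return self.values[name]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path, format: str = "tsv", tissue: str = "OTHER"
) -> ExpressionMatrix:
    """Read a probe x sample expression matrix.

    ``tsv``: first column ``probe_id``, remaining columns sample ids,
    numeric body.  ``geo_series_matrix``: the tab-separated block between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` of a
    GEO series-matrix file; quoted identifiers are tolerated.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    elif format == "geo_series_matrix":
        df = _read_geo_series_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate probe id {dup!r}")
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at probe {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, tissue=tissue, normalized=False)


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    lines = []
    inside = False
    with open(path) as fh:
        for line in fh:
            s = line.strip("\n")
            if s.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if s.startswith("!series_matrix_table_end"):
                inside = False
                break
            if inside:
                lines.append(s)
    if not lines:
        raise ParseError(f"{path}: no series-matrix table block found")
    rows = [[c.strip().strip('"') for c in ln.split("\t")] for ln in lines if ln]
    header = rows[0][1:]
    index, body = [], []
    for r in rows[1:]:
        index.append(r[0])
        body.append(r[1:])
    df = pd.DataFrame(body, index=index, columns=header)
    return df.apply(pd.to_numeric)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_probe_annotation(path) -> ProbeAnnotation:
    """Two-column TSV ``probe_id<TAB>gene_symbol``; empty symbol = unannotated."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (probe_id, gene_symbol)")
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate probe id {dup!r}")
    mapping = {
        p: (g if g else None) for p, g in zip(probes, df.iloc[:, 1])
    }
    return ProbeAnnotation(mapping=mapping)


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    df = pd.DataFrame(
        {"probe_id": list(ann.mapping), "gene_symbol": [v or "" for v in ann.mapping.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_trait_table(path, gender_labels: Mapping[str, int] | None = None) -> TraitTable:
    """Read a sample x trait TSV (first column ``sample_id``; empty = missing).

    ``gender_labels`` maps textual gender codes to 0/1 (e.g. ``{"M": 0, "F": 1}``);
    numeric 0/1 gender columns need no mapping.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    out = {}
    for col in df.columns:
        raw = df[col].replace("", np.nan)
        if col == "gender" and gender_labels:
            def _code(v):
                if pd.isna(v):
                    return np.nan
                if v in gender_labels:
                    return float(gender_labels[v])
                try:
                    f = float(v)
                except ValueError:
                    raise ParseError(f"{path}: unknown gender label {v!r}") from None
                if f not in (0.0, 1.0):
                    raise ParseError(f"{path}: unknown gender label {v!r}")
                return f
            out[col] = raw.map(_code)
        else:
            try:
                # numpy's str->float conversion is correctly rounded, so
                # %.17g output round-trips bit-exactly
                out[col] = raw.astype(float)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: non-numeric value in column {col!r} ({exc})") from exc
    return TraitTable(values=pd.DataFrame(out, index=df.index))


def write_trait_table(t: TraitTable, path) -> None:
    df = t.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean order-statistic reference.

    The reference distribution is the across-sample mean of the sorted
    value vectors.  Ties within a sample receive the mean of the
    reference values at the tied ranks, so within-sample rank order
    (including ties) is preserved exactly.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    n_probes, n_samples = m.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        start = np.concatenate([[0], np.cumsum(counts)[:-1]])
        group_mean = (csum[start + counts] - csum[start]) / counts
        out[:, j] = group_mean[inv]
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=df, tissue=m.tissue, normalized=True)


# ---------------------------------------------------------------------------
# Sample quality control
# ---------------------------------------------------------------------------

@dataclass
class QCParams:
    """Thresholds for per-sample quality control.

    The original QC screened median probe intensity, correlation with the
    other samples of the same tissue, housekeeping-gene behaviour, and a
    principal-component scan; the exact thresholds were never published,
    so the defaults here are conventional and fully configurable.
    """

    min_mean_intersample_correlation: float = 0.80
    median_intensity_z_min: float = -3.0
    pca_outlier_sd: float = 4.0
    housekeeping_probe_ids: list | None = None
    housekeeping_z_max: float = 4.0
    check_correlation: bool = True
    check_median_intensity: bool = True
    check_pca: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_mean_intersample_correlation <= 1.0:
            raise ValueError("min_mean_intersample_correlation must be in [0, 1]")
        if self.pca_outlier_sd <= 0:
            raise ValueError("pca_outlier_sd must be positive")


@dataclass
class QCReport:
    """Per-sample QC metrics and the flagged samples with reasons."""

    metrics: pd.DataFrame
    flagged: dict = field(default_factory=dict)

    @property
    def flagged_samples(self) -> list:
        return list(self.flagged)


def sample_qc(m: ExpressionMatrix, params: QCParams | None = None) -> tuple[ExpressionMatrix, QCReport]:
    """Screen samples on median intensity, inter-sample correlation, PCA,
    and (when a probe list is supplied) housekeeping rank behaviour.

    All metrics are computed once on the full input matrix and every
    enabled criterion is applied in a single pass; a sample failing any
    criterion is removed.  Raises if every sample would be removed.
    """
    params = params or QCParams()
    n_probes, n_samples = m.shape
    if n_samples < 3:
        raise ValueError("sample QC needs at least 3 samples")
    X = m.values.to_numpy(dtype=float)
    sample_ids = m.sample_ids

    med = np.median(X, axis=0)
    med_sd = med.std(ddof=1)
    med_z = (med - med.mean()) / med_sd if med_sd > 0 else np.zeros(n_samples)

    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, np.nan)
    mean_corr = np.nanmean(C, axis=1)

    # PCA over samples (observations = samples, variables = probes)
    Xc = (X - X.mean(axis=1, keepdims=True)).T
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :2] * S[:2]
    pc_sd = scores.std(axis=0, ddof=1)
    pc_sd[pc_sd == 0] = 1.0
    pc_z = (scores - scores.mean(axis=0)) / pc_sd

    metrics = pd.DataFrame(
        {
            "median_intensity": med,
            "median_intensity_z": med_z,
            "mean_intersample_correlation": mean_corr,
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    hk = params.housekeeping_probe_ids
    if hk:
        present = [p for p in hk if p in m.values.index]
        if not present:
            logger.warning("no housekeeping probes found in matrix; criterion skipped")
            hk = None
        else:
            from scipy.stats import rankdata

            ranks = np.apply_along_axis(rankdata, 0, X) / n_probes
            hk_idx = [m.values.index.get_loc(p) for p in present]
            hk_mean_rank = ranks[hk_idx, :].mean(axis=0)
            sd = hk_mean_rank.std(ddof=1)
            hk_z = (hk_mean_rank - hk_mean_rank.mean()) / sd if sd > 0 else np.zeros(n_samples)
            metrics["housekeeping_mean_rank"] = hk_mean_rank
            metrics["housekeeping_rank_z"] = hk_z

    flagged: dict[str, list[str]] = {}

    def _flag(i: int, reason: str) -> None:
        flagged.setdefault(sample_ids[i], []).append(reason)

    for i in range(n_samples):
        if params.check_median_intensity and med_z[i] < params.median_intensity_z_min:
            _flag(i, f"median intensity z={med_z[i]:.2f} < {params.median_intensity_z_min}")
        if params.check_correlation and mean_corr[i] < params.min_mean_intersample_correlation:
            _flag(i, f"mean inter-sample correlation {mean_corr[i]:.3f} < "
                     f"{params.min_mean_intersample_correlation}")
        if params.check_pca and np.any(np.abs(pc_z[i]) > params.pca_outlier_sd):
            _flag(i, f"PC outlier |z|={np.abs(pc_z[i]).max():.2f} > {params.pca_outlier_sd}")
        if hk and abs(metrics["housekeeping_rank_z"].iloc[i]) > params.housekeeping_z_max:
            _flag(i, "housekeeping rank deviation")

    keep = [s for s in sample_ids if s not in flagged]
    if not keep:
        raise ValueError("sample QC flagged every sample; refusing to return an empty matrix")
    if flagged:
        logger.info("sample QC removed %d/%d samples: %s", len(flagged), n_samples, sorted(flagged))
    out = ExpressionMatrix(values=m.values[keep], tissue=m.tissue, normalized=m.normalized)
    return out, QCReport(metrics=metrics, flagged=flagged)
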