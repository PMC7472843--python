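"""Survival datasets with clinical covariates and gene-expression matrices.

This module holds the domain container (:class:`SurvivalDataset`), ingestion of
tab-separated expression/clinical matrices in the pan-cancer Xena dialect
(genes in rows, samples in columns), quality-control gene filters,
standardization, and the low-/high-censored dataset classification used to
stratify cancers by how informative their follow-up is.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "QCReport",
    "CensoringClass",
    "Standardizer",
    "load_expression_matrix",
    "load_clinical",
    "merge_dataset",
    "qc_filter_genes",
    "standardize",
    "classify_censoring",
    "save_dataset",
    "load_dataset",
]

DEFAULT_STATUS_MAP = {
    "0": 0, "1": 1, "alive": 0, "dead": 1, "living": 0, "deceased": 1,
    "censored": 0, "event": 1, "false": 0, "true": 1,
}


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass
class Standardizer:
    """Column means/scales learned on one dataset, re-applicable to new rows.

    Keeping the transform separate from the data makes it possible to learn
    centering/scaling on a training fold and apply it to held-out samples.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    g_mean: np.ndarray
    g_scale: np.ndarray

    def apply(self, X: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (X - self.x_mean) / self.x_scale, (G - self.g_mean) / self.g_scale


@dataclass
class SurvivalDataset:
    """Aligned survival outcomes, clinical covariates, and expression matrix.

    Attributes
    ----------
    sample_ids : list of str
    times : (n,) array of positive follow-up times (unit in ``metadata``).
    status : (n,) int array; 1 = event observed, 0 = censored.
    X : (n, p) clinical covariate matrix.
    clinical_names : list of p column names.
    G : (n, m) gene-expression matrix.
    gene_ids : list of m gene identifiers.
    standardized : whether columns of X and G are mean-0 / variance-1.
    standardizer : the transform used, when ``standardized`` is True.
    metadata : free-form provenance (time unit, merge counts, ...).
    """

    sample_ids: list[str]
    times: np.ndarray
    status: np.ndarray
    X: np.ndarray
    clinical_names: list[str]
    G: np.ndarray
    gene_ids: list[str]
    standardized: bool = False
    standardizer: Standardizer | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        if self.X.shape[0] != self.n and self.X.size == 0:
            self.X = np.empty((self.n, 0))
        if self.G.shape[0] != self.n and self.G.size == 0:
            self.G = np.empty((self.n, 0))
        self.validate()

    # -- basic shape properties ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def event_fraction(self) -> float:
        return float(self.status.mean())

    def validate(self) -> None:
        n = self.n
        if len(self.sample_ids) != n or len(self.status) != n:
            raise DataError("sample_ids, times and status must have equal length")
        if self.X.shape[0] != n or self.G.shape[0] != n:
            raise DataError("X and G must have one row per sample")
        if self.X.shape[1] != len(self.clinical_names):
            raise DataError("clinical_names length does not match X columns")
        if self.G.shape[1] != len(self.gene_ids):
            raise DataError("gene_ids length does not match G columns")
        if np.any(self.times <= 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(self.times <= 0)]
            raise DataError(f"non-positive survival times for samples {bad}")
        if not np.isin(self.status, [0, 1]).all():
            raise DataError("status must contain only 0 (censored) and 1 (event)")
        if (self.X.size and not np.isfinite(self.X).all()) or (
            self.G.size and not np.isfinite(self.G).all()
        ):
            raise DataError("X/G contain missing or non-finite values")
        if self.standardized:
            for mat, names in ((self.X, self.clinical_names), (self.G, self.gene_ids)):
                if mat.shape[1] == 0:
                    continue
                mu = np.abs(mat.mean(axis=0))
                var = mat.var(axis=0, ddof=1)
                if mu.max() > 1e-8 or np.abs(var - 1).max() > 1e-6:
                    raise DataError("standardized flag set but columns are not mean-0/var-1")

    def subset(self, rows: np.ndarray, genes: np.ndarray | Sequence[int] | None = None) -> "SurvivalDataset":
        """Row (and optionally gene-column) subset; keeps standardization flag
        only when it still holds (it generally does not on a subset)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        G = self.G[rows]
        gene_ids = self.gene_ids
        if genes is not None:
            genes = np.asarray(genes)
            G = G[:, genes]
            gene_ids = [self.gene_ids[j] for j in genes]
        meta = dict(self.metadata)
        if self.standardized or self.metadata.get("standardized_parent"):
            meta["standardized_parent"] = True  # columns remain near mean-0/var-1
        return SurvivalDataset(
            sample_ids=[self.sample_ids[i] for i in rows],
            times=self.times[rows],
            status=self.status[rows],
            X=self.X[rows],
            clinical_names=list(self.clinical_names),
            G=G,
            gene_ids=gene_ids,
            standardized=False,
            standardizer=self.standardizer,
            metadata=meta,
        )

    def replace(self, **changes) -> "SurvivalDataset":
        return dataclasses.replace(self, **changes)


@dataclass
class QCReport:
    """Bookkeeping for the sequential gene filters."""

    n_genes_in: int
    n_removed_zero: int
    n_removed_lowvar: int
    n_genes_out: int
    max_zero_frac: float
    var_quantile: float

    def __post_init__(self) -> None:
        assert self.n_genes_out == self.n_genes_in - self.n_removed_zero - self.n_removed_lowvar
        assert min(self.n_genes_in, self.n_removed_zero, self.n_removed_lowvar, self.n_genes_out) >= 0


@dataclass
class CensoringClass:
    """Low-/high-censored dataset label with the thresholds that produced it."""

    label: str  # "low_censored" | "high_censored"
    n: int
    event_fraction: float
    n_min: int
    frac_threshold: float
    criterion: str


# -----------------------------------------------------------------------------
# ingestion
# -----------------------------------------------------------------------------

def load_expression_matrix(path: str | Path, dialect: str = "genes_by_samples") -> pd.DataFrame:
    """Read a tab-separated expression matrix, returning samples-in-rows.

    The ``genes_by_samples`` dialect is the pan-cancer Xena layout: first
    column gene identifiers, remaining columns one per sample.
    """
    if dialect not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise DataError(f"duplicated {'gene' if dialect == 'genes_by_samples' else 'sample'} identifiers: {dup}")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ].tolist()
    if non_numeric:
        for col in non_numeric:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
            raise DataError(f"non-numeric cells in column {col!r}, rows {bad_rows[:5]}")
    if df.isna().any().any():
        raise DataError("expression matrix contains missing values")
    if dialect == "genes_by_samples":
        df = df.T  # samples in rows
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_clinical(
    path: str | Path,
    sample_col: str = "sample",
    time_col: str = "OS.time",
    status_col: str = "OS.event",
    status_map: Mapping[str, int] | None = None,
    categorical: Sequence[str] = ("gender", "stage", "grade"),
    stage_ordinal: bool = False,
) -> pd.DataFrame:
    """Read a per-sample clinical TSV into a numeric design table.

    Rows missing the sample id, time or status are dropped (count recorded in
    ``df.attrs['n_dropped']``); categorical covariates are dummy-coded against
    the lexicographically first level, or mapped to integer codes for stage
    when ``stage_ordinal`` is set.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    for col in (sample_col, time_col, status_col):
        if col not in raw.columns:
            raise DataError(f"required clinical column {col!r} missing")
    n0 = len(raw)
    raw = raw.dropna(subset=[sample_col, time_col, status_col])
    n_dropped = n0 - len(raw)

    status_map = {**DEFAULT_STATUS_MAP, **{k.lower(): v for k, v in (status_map or {}).items()}}
    status = raw[status_col].astype(str).str.strip().str.lower().map(status_map)
    if status.isna().any():
        bad = raw.loc[status.isna(), status_col].unique().tolist()
        raise DataError(f"unmappable status values: {bad}")

    times = pd.to_numeric(raw[time_col], errors="coerce")
    if times.isna().any():
        raise DataError("non-numeric survival times")
    if (times <= 0).any():
        bad = raw.loc[times <= 0, sample_col].tolist()
        raise DataError(f"non-positive survival times for samples {bad}")

    out = pd.DataFrame({"sample": raw[sample_col].astype(str), "time": times.values,
                        "status": status.astype(int).values})
    covars = [c for c in raw.columns if c not in (sample_col, time_col, status_col)]
    for col in covars:
        vals = raw[col]
        if col in categorical or not pd.api.types.is_numeric_dtype(vals):
            if stage_ordinal and col in ("stage", "grade"):
                levels = sorted(vals.dropna().astype(str).unique())
                out[col] = vals.astype(str).map({lv: i for i, lv in enumerate(levels)}).values
            else:
                dummies = pd.get_dummies(vals.astype(str), prefix=col, drop_first=True, dtype=float)
                for dcol in dummies.columns:
                    out[dcol] = dummies[dcol].values
        else:
            out[col] = pd.to_numeric(vals).values
    out = out.dropna()
    out.attrs["n_dropped"] = n_dropped + (len(raw) - len(out))
    return out.reset_index(drop=True)


def merge_dataset(expr: pd.DataFrame, clin: pd.DataFrame, time_unit: str = "unknown") -> SurvivalDataset:
    """Intersect expression and clinical tables on sample id, aligned in the
    clinical table's order."""
    clin_ids = clin["sample"].tolist()
    expr_ids = set(expr.index)
    common = [s for s in clin_ids if s in expr_ids]
    if not common:
        raise DataError("no samples in common between expression and clinical tables")
    clin_sub = clin.set_index("sample").loc[common]
    expr_sub = expr.loc[common]
    covar_cols = [c for c in clin_sub.columns if c not in ("time", "status")]
    return SurvivalDataset(
        sample_ids=common,
        times=clin_sub["time"].to_numpy(float),
        status=clin_sub["status"].to_numpy(int),
        X=clin_sub[covar_cols].to_numpy(float) if covar_cols else np.empty((len(common), 0)),
        clinical_names=covar_cols,
        G=expr_sub.to_numpy(float),
        gene_ids=[str(g) for g in expr_sub.columns],
        metadata={
            "time_unit": time_unit,
            "n_expr": len(expr), "n_clin": len(clin), "n_merged": len(common),
        },
    )


# -----------------------------------------------------------------------------
# quality control / standardization / censoring class
# -----------------------------------------------------------------------------

def qc_filter_genes(
    ds: SurvivalDataset, max_zero_frac: float = 0.5, var_quantile: float = 0.2
) -> tuple[SurvivalDataset, QCReport]:
    """Sequential gene filters: drop genes with zero-expression fraction
    strictly above ``max_zero_frac``, then, among the survivors, genes whose
    variance lies strictly below the ``var_quantile`` empirical quantile of
    survivor variances.

    Order matters: the variance quantile is computed over the genes that
    survive the zero filter only.
    """
    if ds.standardized:
        raise DataError("qc_filter_genes expects unstandardized expression values")
    G = ds.G
    m_in = ds.m
    zero_frac = (G == 0).mean(axis=0)
    keep_zero = zero_frac <= max_zero_frac  # "more than 50%" is strict
    n_removed_zero = int((~keep_zero).sum())

    surv_idx = np.flatnonzero(keep_zero)
    n_removed_lowvar = 0
    if surv_idx.size and var_quantile > 0:
        variances = G[:, surv_idx].var(axis=0, ddof=1)
        cutoff = np.quantile(variances, var_quantile)
        keep_var = variances >= cutoff  # strictly below the quantile removed
        n_removed_lowvar = int((~keep_var).sum())
        surv_idx = surv_idx[keep_var]
    if surv_idx.size == 0:
        raise DataError(
            "all genes removed by QC; relax max_zero_frac/var_quantile"
        )
    out = ds.subset(np.arange(ds.n), genes=surv_idx)
    report = QCReport(
        n_genes_in=m_in,
        n_removed_zero=n_removed_zero,
        n_removed_lowvar=n_removed_lowvar,
        n_genes_out=len(surv_idx),
        max_zero_frac=max_zero_frac,
        var_quantile=var_quantile,
    )
    return out, report


def standardize(ds: SurvivalDataset) -> SurvivalDataset:
    """Center and scale every clinical and expression column to mean 0,
    variance 1 (sample variance, ddof=1), recording the transform."""
    def _fit(mat: np.ndarray, names: Sequence[str]):
        if mat.shape[1] == 0:
            return np.empty(0), np.ones(0)
        mean = mat.mean(axis=0)
        scale = mat.std(axis=0, ddof=1)
        const = np.flatnonzero(scale < 1e-12)
        if const.size:
            raise DataError(f"constant columns cannot be standardized: {[names[j] for j in const]}")
        return mean, scale

    x_mean, x_scale = _fit(ds.X, ds.clinical_names)
    g_mean, g_scale = _fit(ds.G, ds.gene_ids)
    std = Standardizer(x_mean, x_scale, g_mean, g_scale)
    Xs, Gs = std.apply(ds.X, ds.G)
    return ds.replace(X=Xs, G=Gs, standardized=True, standardizer=std)


def classify_censoring(
    ds: SurvivalDataset,
    n_min: int = 175,
    frac_threshold: float = 0.15,
    criterion: str = "event_fraction_ge",
) -> CensoringClass:
    """Label a dataset low- or high-censored.

    A dataset is low-censored when n is strictly greater than ``n_min`` and
    the follow-up fraction rule holds. Two readings of the fraction rule are
    supported (the phrase "proportion of censored event less than 15%" is
    ambiguous for observational registries whose censored fractions are
    typically far above 15%):

    - ``event_fraction_ge`` (default): event fraction >= ``frac_threshold``,
      i.e. enough observed events for stable evaluation;
    - ``censored_fraction_lt``: censored fraction < ``frac_threshold``.
    """
    ev = ds.event_fraction
    if criterion == "event_fraction_ge":
        frac_ok = ev >= frac_threshold
    elif criterion == "censored_fraction_lt":
        frac_ok = (1.0 - ev) < frac_threshold
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    label = "low_censored" if (ds.n > n_min and frac_ok) else "high_censored"
    return CensoringClass(
        label=label, n=ds.n, event_fraction=ev,
        n_min=n_min, frac_threshold=frac_threshold, criterion=criterion,
    )


# -----------------------------------------------------------------------------
# round-trip container
# -----------------------------------------------------------------------------

def save_dataset(ds: SurvivalDataset, path: str | Path) -> None:
    """Serialize to a compressed ``.npz`` (bit-exact round trip)."""
    np.savez_compressed(
        path,
        sample_ids=np.array(ds.sample_ids, dtype=object),
        times=ds.times,
        status=ds.status,
        X=ds.X,
        clinical_names=np.array(ds.clinical_names, dtype=object),
        G=ds.G,
        gene_ids=np.array(ds.gene_ids, dtype=object),
        standardized=np.array(ds.standardized),
        metadata=np.array(repr(ds.metadata), dtype=object),
    )


def load_dataset(path: str | Path) -> SurvivalDataset:
    with np.load(path, allow_pickle=True) as z:
        import ast

        return SurvivalDataset(
            sample_ids=[str(s) for s in z["sample_ids"]],
            times=z["times"],
            status=z["status"],
            X=z["X"],
            clinical_names=[str(s) for s in z["clinical_names"]],
            G=z["G"],
            gene_ids=[str(s) for s in z["gene_ids"]],
            standardized=bool(z["standardized"]),
            metadata=ast.literal_eval(str(z["metadata"])),
        )
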