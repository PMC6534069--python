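"""Variable normalization for dietary and metabolite tables.

The chain applied to metabolite intensities is: below-LOD imputation with the
per-variable minimum, median rescaling, rank-based inverse-normal transform
(INT), and a Shapiro-Wilk normality screen. Dietary variables additionally
get the residual method (adjustment for total caloric intake and gender,
then standardization) and deduplication of highly correlated clusters
(Spearman > 0.9, one representative kept per connected component).

Metabolites deliberately do NOT receive the energy/gender residual
adjustment; that step is specific to nutrient-intake variables, whose raw
scale is confounded by total intake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import FeatureTable, SampleMetadata

__all__ = [
    "NormalizationReport",
    "impute_below_lod",
    "median_rescale",
    "inverse_normal_transform",
    "int_table",
    "shapiro_screen",
    "residual_adjust",
    "dedup_correlated",
    "preprocess_diet",
    "preprocess_metabolites",
]

BLOM_C = 3.0 / 8.0


@dataclass
class NormalizationReport:
    """Per-variable bookkeeping of the normalization chain."""

    imputed_count: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)  # id -> reason
    shapiro_p: dict[str, float] = field(default_factory=dict)
    cluster_id: dict[str, int] = field(default_factory=dict)
    representative: dict[str, str] = field(default_factory=dict)  # id -> rep id

    def kept(self, variable_id: str) -> bool:
        return variable_id not in self.dropped

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(
            set(self.imputed_count) | set(self.dropped) | set(self.shapiro_p)
            | set(self.cluster_id) | set(self.representative)
        )
        return pd.DataFrame(
            {
                "imputed_count": [self.imputed_count.get(v, 0) for v in ids],
                "shapiro_p": [self.shapiro_p.get(v, np.nan) for v in ids],
                "kept": [self.kept(v) for v in ids],
                "drop_reason": [self.dropped.get(v, "") for v in ids],
                "cluster_id": [self.cluster_id.get(v, -1) for v in ids],
                "representative": [self.representative.get(v, "") for v in ids],
            },
            index=pd.Index(ids, name="variable_id"),
        )


def impute_below_lod(
    metabolites: FeatureTable, report: NormalizationReport | None = None
) -> tuple[FeatureTable, NormalizationReport]:
    """Replace missing (below limit-of-detection) cells with the variable minimum.

    Variables with no observed value at all are dropped with a warning.
    """
    report = report or NormalizationReport()
    df = metabolites.data.copy()
    keep = []
    for col in df.columns:
        x = df[col]
        n_missing = int(x.isna().sum())
        report.imputed_count[col] = n_missing
        if n_missing == len(x):
            report.dropped[col] = "all values missing"
            warnings.warn(f"variable {col!r} has no observed values; dropped")
            continue
        if n_missing:
            df[col] = x.fillna(x.min())
        keep.append(col)
    return FeatureTable(df[keep], metabolites.variable_meta), report


def median_rescale(metabolites: FeatureTable) -> FeatureTable:
    """Divide each variable by its median so every median becomes 1."""
    df = metabolites.data
    med = df.median(axis=0)
    zero = med[med == 0]
    if len(zero):
        raise ValueError(f"zero median for variables: {list(zero.index)}")
    return FeatureTable(df / med, metabolites.variable_meta)


def inverse_normal_transform(x: np.ndarray, c: float = BLOM_C) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset c = 3/8.

    Maps x to Phi^{-1}((rank - c) / (n - 2c + 1)) with average ranks for
    ties. Monotone in the input; invariant to strictly increasing
    transformations of x.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expects a vector")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.isnan(x).any():
        raise ValueError("missing values must be imputed before INT")
    if np.ptp(x) == 0:
        raise ValueError("constant vector has no rank variation")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))


def int_table(table: FeatureTable) -> FeatureTable:
    """Apply the inverse-normal transform column-wise; constant columns error."""
    out = {col: inverse_normal_transform(table.data[col].to_numpy())
           for col in table.data.columns}
    return FeatureTable(pd.DataFrame(out, index=table.data.index),
                        table.variable_meta)


def shapiro_screen(
    table: FeatureTable,
    alpha: float = 0.05,
    report: NormalizationReport | None = None,
) -> tuple[FeatureTable, NormalizationReport]:
    """Drop variables whose Shapiro-Wilk p-value falls below ``alpha``.

    Intended for INT-transformed variables: a failing variable signals
    heavy ties or near-zero variability that the rank transform could not
    repair.
    """
    report = report or NormalizationReport()
    if table.n_samples < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    keep = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000 / ties
        for col in table.data.columns:
            p = float(stats.shapiro(table.data[col].to_numpy()).pvalue)
            report.shapiro_p[col] = p
            if p < alpha:
                report.dropped[col] = f"shapiro p={p:.3g} < {alpha}"
            else:
                keep.append(col)
    return table.select_variables(keep), report


def residual_adjust(
    diet: FeatureTable,
    meta: SampleMetadata,
    log_kcal: bool = False,
    report: NormalizationReport | None = None,
) -> tuple[FeatureTable, NormalizationReport]:
    """Residual method: regress out total caloric intake and gender, standardize.

    Each variable is replaced by its least-squares residual on
    [1, total_kcal, gender], then scaled to mean 0 and SD 1. Variables whose
    residuals are (numerically) constant are dropped with a warning. In a
    single-gender cohort the gender column is collinear with the intercept
    and is dropped from the design.
    """
    report = report or NormalizationReport()
    if list(meta.sample_ids) != list(diet.sample_ids):
        raise ValueError("metadata and diet table are not sample-aligned")
    n = diet.n_samples
    kcal = pd.to_numeric(meta.data["total_kcal"]).to_numpy(dtype=float)
    if log_kcal:
        kcal = np.log(kcal)
    gender = pd.factorize(meta.data["gender"])[0].astype(float)
    cols = [np.ones(n), kcal]
    if np.ptp(gender) > 0:
        cols.append(gender)
    else:
        warnings.warn("single-gender cohort: gender term dropped from design")
    X = np.column_stack(cols)
    # hat-matrix residual projection, one solve for all variables
    Y = diet.values
    if np.isnan(Y).any():
        raise ValueError("residual adjustment cannot handle missing values")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    sd = resid.std(axis=0, ddof=1)
    keep = sd > 1e-10 * max(1.0, np.abs(Y).max())
    out_cols = []
    for j, col in enumerate(diet.data.columns):
        if not keep[j]:
            report.dropped[col] = "zero residual variance after adjustment"
            warnings.warn(f"variable {col!r} fully explained by covariates; dropped")
            continue
        out_cols.append(col)
    Z = resid[:, keep]
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    return (
        FeatureTable(pd.DataFrame(Z, index=diet.data.index, columns=out_cols),
                     diet.variable_meta),
        report,
    )


def dedup_correlated(
    table: FeatureTable,
    rho: float = 0.9,
    report: NormalizationReport | None = None,
) -> tuple[FeatureTable, NormalizationReport]:
    """Collapse clusters of near-identical variables to one representative.

    Variables are linked when their pairwise Spearman correlation exceeds
    ``rho`` (signed: near-identical variables are positively associated);
    clusters are the connected components of that graph. The representative
    is the member with the highest mean Spearman correlation to its cluster
    (ties broken by variable id); all other members are dropped, and the
    member -> representative map is recorded.
    """
    report = report or NormalizationReport()
    if table.n_variables < 2:
        return table, report
    ids = list(table.data.columns)
    corr, _ = stats.spearmanr(table.values)
    corr = np.atleast_2d(corr)
    adj = (corr > rho) & ~np.eye(len(ids), dtype=bool)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    keep = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if members.size == 1:
            v = ids[members[0]]
            report.cluster_id[v] = comp
            report.representative[v] = v
            keep.append(v)
            continue
        sub = corr[np.ix_(members, members)]
        mean_rho = (sub.sum(axis=1) - 1.0) / (members.size - 1)
        # highest mean correlation wins; lexicographically first id on ties
        best = min(
            range(members.size),
            key=lambda i: (-round(mean_rho[i], 12), ids[members[i]]),
        )
        rep = ids[members[best]]
        for i in members:
            report.cluster_id[ids[i]] = comp
            report.representative[ids[i]] = rep
            if ids[i] != rep:
                report.dropped[ids[i]] = f"deduplicated into {rep}"
        keep.append(rep)
    keep = [v for v in ids if v in set(keep)]  # preserve original order
    return table.select_variables(keep), report


def preprocess_metabolites(
    metabolites: FeatureTable, alpha: float = 0.05
) -> tuple[FeatureTable, NormalizationReport]:
    """Full metabolite chain: LOD imputation, median rescale, INT, Shapiro screen."""
    report = NormalizationReport()
    t, report = impute_below_lod(metabolites, report)
    t = median_rescale(t)
    t = int_table(t)
    t, report = shapiro_screen(t, alpha=alpha, report=report)
    return t, report


def preprocess_diet(
    diet: FeatureTable,
    meta: SampleMetadata,
    alpha: float = 0.05,
    rho: float = 0.9,
) -> tuple[FeatureTable, NormalizationReport]:
    """Full diet chain: INT, Shapiro screen, residual method, dedup at Spearman rho."""
    report = NormalizationReport()
    t = int_table(diet)
    t, report = shapiro_screen(t, alpha=alpha, report=report)
    t, report = residual_adjust(t, meta, report=report)
    t, report = dedup_correlated(t, rho=rho, report=report)
    return t, report
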