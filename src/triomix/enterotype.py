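"""Enterotype discovery and enterotype-stratified diet-metabolite analysis.

Enterotypes are discrete clusters of gut community composition. They are
found by partitioning-around-medoids (PAM) clustering under ecological
distances (Euclidean on proportions, Bray-Curtis, binary Jaccard), with the
distance and cluster number chosen by maximum average silhouette width over
a grid. Clusters are characterized by Welch two-sample t-tests on
INT-transformed taxon (and family) abundances and metabolites, and
diet x enterotype interactions on metabolites are tested pair-by-pair with
ordinary least squares (m ~ 1 + d + E + d:E).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa
from skbio.stats.distance import DistanceMatrix
from sklearn.metrics import silhouette_score

from .containers import CompositionMatrix, FeatureTable
from .preprocess import inverse_normal_transform

__all__ = ["EnterotypeModel", "InteractionResult", "ecological_distance",
           "pam_cluster", "choose_enterotypes", "enterotype_characterize",
           "interaction_scan", "stratified_association"]

logger = logging.getLogger(__name__)

DISTANCES = ("euclidean", "bray-curtis", "jaccard")


@dataclass
class EnterotypeModel:
    """A PAM clustering of samples under one ecological distance."""

    distance_name: str
    k: int
    medoid_ids: list[str]
    labels: pd.Series  # sample_id -> 1..k
    silhouette: float
    pcoa_coords: pd.DataFrame | None = None  # first two axes
    pcoa_fractions: tuple[float, float] | None = None
    silhouette_grid: pd.DataFrame | None = None
    weak_structure: bool = False
    total_cost: float = field(default=np.nan)

    def summary(self) -> str:
        sizes = self.labels.value_counts().sort_index()
        lines = [
            f"Enterotype model: PAM, {self.distance_name} distance, k={self.k}",
            f"  average silhouette width: {self.silhouette:.3f}"
            + ("  (weak cluster structure)" if self.weak_structure else ""),
            "  cluster sizes: " + ", ".join(
                f"E{c}={n}" for c, n in sizes.items()),
            "  medoids: " + ", ".join(self.medoid_ids),
        ]
        if self.pcoa_fractions is not None:
            lines.append(
                f"  PCoA axis variance: {self.pcoa_fractions[0]:.1%}, "
                f"{self.pcoa_fractions[1]:.1%}")
        return "\n".join(lines)


def ecological_distance(composition: CompositionMatrix, name: str) -> np.ndarray:
    """Pairwise distances between samples: euclidean, bray-curtis or jaccard.

    Jaccard is the classical binary form on presence/absence (proportion
    greater than zero); Bray-Curtis is abundance-weighted.
    """
    P = composition.values
    if name == "euclidean":
        return squareform(pdist(P, metric="euclidean"))
    if name == "bray-curtis":
        return squareform(pdist(P, metric="braycurtis"))
    if name == "jaccard":
        return squareform(pdist(P > 0, metric="jaccard"))
    raise ValueError(f"unknown distance {name!r}; choose from {DISTANCES}")


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Deterministic greedy BUILD initialization."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        # gain of adding candidate c: sum of reductions in distance-to-medoid
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return sorted(medoids)


def pam_cluster(D: np.ndarray, k: int, sample_ids=None,
                distance_name: str = "custom") -> EnterotypeModel:
    """Classic PAM (BUILD + SWAP) k-medoids on a distance matrix.

    Entirely deterministic: greedy BUILD start, then best-improvement SWAP
    (evaluate every medoid/non-medoid exchange, apply the single best) until
    no swap lowers the total within-cluster distance to medoid.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if not (2 <= k < n):
        raise ValueError("need 2 <= k < n")

    def cost(meds):
        return float(D[:, meds].min(axis=1).sum())

    from math import comb
    if comb(n, k) <= 20000:
        # small search space: the optimum is affordable exactly, so the
        # swap heuristic's occasional local traps are avoided outright
        from itertools import combinations
        medoids, best = None, np.inf
        for cand in combinations(range(n), k):
            c = cost(list(cand))
            if c < best - 1e-12:
                medoids, best = list(cand), c
    else:
        medoids = _pam_build(D, k)
        best = cost(medoids)
        while True:  # best-improvement SWAP
            best_swap, best_cost = None, best
            for mi in range(k):
                for h in range(n):
                    if h in medoids:
                        continue
                    cand = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                    c = cost(cand)
                    if c < best_cost - 1e-12:
                        best_swap, best_cost = cand, c
            if best_swap is None:
                break
            medoids, best = best_swap, best_cost
    assign = np.argmin(D[:, medoids], axis=1)
    ids = (list(sample_ids) if sample_ids is not None
           else [str(i) for i in range(n)])
    labels = pd.Series(assign + 1, index=ids, name="enterotype")
    if len(np.unique(assign)) < 2:  # degenerate: one medoid captured all
        sil = -1.0
    else:
        sil = float(silhouette_score(D, assign, metric="precomputed"))
    return EnterotypeModel(
        distance_name=distance_name, k=k,
        medoid_ids=[ids[m] for m in medoids],
        labels=labels, silhouette=sil, total_cost=best,
    )


def choose_enterotypes(composition: CompositionMatrix,
                       distances=DISTANCES,
                       k_range=range(2, 7)) -> EnterotypeModel:
    """Fit PAM over a (distance, k) grid; keep the max-silhouette model.

    The chosen model gets classical PCoA coordinates (negative eigenvalues
    zeroed) on its distance; a maximum silhouette below 0.25 is flagged as
    weak cluster structure.
    """
    ids = composition.sample_ids
    rows = []
    best_model = None
    for name in distances:
        D = ecological_distance(composition, name)
        for k in k_range:
            model = pam_cluster(D, k, sample_ids=ids, distance_name=name)
            rows.append({"distance": name, "k": k,
                         "silhouette": model.silhouette})
            if best_model is None or model.silhouette > best_model.silhouette:
                best_model = model
                best_D = D
    grid = pd.DataFrame(rows)
    best_model.silhouette_grid = grid
    if best_model.silhouette < 0.25:
        best_model.weak_structure = True
        logger.warning("weak cluster structure: max silhouette %.3f",
                       best_model.silhouette)
    ord_res = pcoa(DistanceMatrix(best_D, ids=ids), number_of_dimensions=2)
    coords = ord_res.samples.iloc[:, :2]
    coords.columns = ["PCo1", "PCo2"]
    best_model.pcoa_coords = coords
    fr = ord_res.proportion_explained
    best_model.pcoa_fractions = (float(fr.iloc[0]), float(fr.iloc[1]))
    return best_model


def _welch_table(data: pd.DataFrame, labels: pd.Series,
                 transform: bool = True) -> pd.DataFrame:
    g1 = labels == 1
    g2 = labels == 2
    rows = []
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        if transform:
            try:
                x = inverse_normal_transform(x)
            except ValueError:
                logger.warning("variable %r constant; skipped", col)
                continue
        t, p = stats.ttest_ind(x[g1.to_numpy()], x[g2.to_numpy()],
                               equal_var=False)
        rows.append({"variable": col, "t": float(t), "p": float(p),
                     "mean_e1": float(x[g1.to_numpy()].mean()),
                     "mean_e2": float(x[g2.to_numpy()].mean())})
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def enterotype_characterize(
    composition: CompositionMatrix,
    labels: pd.Series,
    taxa_level_map: dict[str, str] | None = None,
    metabolites: FeatureTable | None = None,
):
    """Two-group Welch t statistics for taxa (and families, and metabolites).

    Abundances are INT-transformed before testing; p-values are unadjusted
    (the variables are heavily correlated, so marginal screening is
    reported as such). Returns (taxon_table, family_table_or_None,
    metabolite_table_or_None), each sorted by p.
    """
    labels = labels.loc[composition.sample_ids]
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValueError("expected exactly 2 enterotypes")
    if counts.min() < 3:
        raise ValueError("enterotype with fewer than 3 samples")
    taxon_tab = _welch_table(composition.proportions, labels)
    family_tab = None
    if taxa_level_map is not None:
        fam = composition.proportions.T.groupby(
            lambda t: taxa_level_map.get(t, "unmapped")).sum().T
        family_tab = _welch_table(fam, labels)
    metab_tab = None
    if metabolites is not None:
        metab_tab = _welch_table(metabolites.data,
                                 labels.loc[metabolites.sample_ids],
                                 transform=False)
    return taxon_tab, family_tab, metab_tab


@dataclass
class InteractionResult:
    """OLS diet x enterotype interaction on one metabolite."""

    diet_id: str
    metabolite_id: str
    interaction_coef: float
    interaction_p: float
    diet_coef: float
    enterotype_coef: float
    slope_e1: float
    slope_e2: float
    n_per_enterotype: tuple[int, int]
    low_power: bool = False


def _ols_interaction(d, m, e):
    """m ~ 1 + d + e + d*e by least squares; t-test on the interaction."""
    n = len(m)
    X = np.column_stack([np.ones(n), d, e, d * e])
    coef, _, rank, _ = np.linalg.lstsq(X, m, rcond=None)
    resid = m - X @ coef
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[3, 3])
    t = coef[3] / se if se > 0 else np.nan
    p = 2.0 * stats.t.sf(abs(t), dof) if np.isfinite(t) else np.nan
    return coef, float(t), float(p), dof


def interaction_scan(diet: FeatureTable, metabolites: FeatureTable,
                     labels: pd.Series,
                     covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Test every (diet, metabolite) pair for a diet x enterotype interaction.

    The model is metabolite ~ 1 + diet + E + diet:E (+ covariates), with E a
    0/1 enterotype indicator; reported p-values are unadjusted two-sided
    t-tests on the interaction term. Per-enterotype simple slopes accompany
    each row. An enterotype with fewer than 10 samples flags the whole scan
    low-power.
    """
    labels = labels.loc[diet.sample_ids]
    if list(diet.sample_ids) != list(metabolites.sample_ids):
        raise ValueError("diet and metabolite tables are not sample-aligned")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError("expected exactly 2 enterotypes")
    e = (labels == uniq[1]).to_numpy(dtype=float)
    n1, n2 = int((e == 0).sum()), int((e == 1).sum())
    low_power = min(n1, n2) < 10
    if low_power:
        logger.warning("enterotype with <10 samples: results low-power")
    rows = []
    M = metabolites.data
    Dt = diet.data
    for d_id in Dt.columns:
        d = Dt[d_id].to_numpy(dtype=float)
        for m_id in M.columns:
            m = M[m_id].to_numpy(dtype=float)
            if covariates is not None:
                C = np.column_stack([np.ones(len(m)), covariates])
                m = m - C @ np.linalg.lstsq(C, m, rcond=None)[0]
            coef, t, p, dof = _ols_interaction(d, m, e)
            rows.append({
                "diet": d_id, "metabolite": m_id,
                "interaction_coef": float(coef[3]), "interaction_p": p,
                "diet_coef": float(coef[1]),
                "enterotype_coef": float(coef[2]),
                "slope_e1": float(coef[1]),
                "slope_e2": float(coef[1] + coef[3]),
                "n_e1": n1, "n_e2": n2, "dof": dof,
                "low_power": low_power,
            })
    return pd.DataFrame(rows)


def stratified_association(x, y, labels) -> pd.DataFrame:
    """Per-stratum least-squares slope, t-test p and Spearman correlation.

    For follow-up displays (e.g. metabolite vs CRP/BMI within enterotype).
    Strata with fewer than 5 samples or constant x are flagged and skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    rows = []
    for s in np.unique(labels):
        mask = labels == s
        xs, ys = x[mask], y[mask]
        row = {"stratum": s, "n": int(mask.sum())}
        if mask.sum() < 5:
            row.update(flag="too few samples", slope=np.nan, p=np.nan,
                       spearman=np.nan)
        elif np.ptp(xs) == 0:
            row.update(flag="constant predictor", slope=np.nan, p=np.nan,
                       spearman=np.nan)
        else:
            res = stats.linregress(xs, ys)
            rho = stats.spearmanr(xs, ys).statistic
            row.update(flag="", slope=float(res.slope),
                       p=float(res.pvalue), spearman=float(rho))
        rows.append(row)
    return pd.DataFrame(rows)
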