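"""Weighted-correlation-network modules for metabolites.

Correlated metabolites are grouped into modules by the weighted-correlation
recipe: an unsigned adjacency ``a_ij = |cor(x_i, x_j)|**beta`` with the soft
power ``beta`` chosen for approximate scale-free topology, the topological
overlap measure (TOM) as network similarity, average-linkage hierarchical
clustering of ``1 - TOM``, and a static branch cut. Branches smaller than
``min_module_size`` are relabeled "unclustered". Each module is summarized
by its eigenvalue: the first principal-component score of its standardized
members, itself standardized and sign-oriented to correlate positively with
the module's mean profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .containers import FeatureTable

__all__ = ["ModuleAssignment", "ModuleEigenvalues", "soft_threshold_power",
           "tom_similarity", "detect_modules", "module_eigenvalues"]

UNCLUSTERED = "unclustered"


@dataclass
class ModuleAssignment:
    """metabolite_id -> module label; label 'unclustered' allowed."""

    labels: dict[str, str]
    soft_power: int
    min_module_size: int
    cut_height: float

    @property
    def module_names(self) -> list[str]:
        return sorted({m for m in self.labels.values() if m != UNCLUSTERED})

    @property
    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for m in self.labels.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module: str) -> list[str]:
        return [v for v, m in self.labels.items() if m == module]


@dataclass
class ModuleEigenvalues:
    """Samples x modules eigenvalue scores plus variance explained."""

    scores: pd.DataFrame
    variance_explained: dict[str, float] = field(default_factory=dict)


def _abs_correlation(table: FeatureTable) -> np.ndarray:
    X = table.values
    if np.isnan(X).any():
        raise ValueError("missing values must be imputed before module detection")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [table.variable_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant metabolites have undefined correlation: {bad}")
    return np.abs(np.corrcoef(X, rowvar=False))


def soft_threshold_power(
    table: FeatureTable,
    candidate_powers=range(1, 21),
    target_r2: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Pick the smallest soft power giving scale-free topology fit R^2 >= target.

    For each candidate beta the adjacency is ``|cor|**beta``; connectivity
    ``k_i`` is the row sum excluding self; the fit is the R^2 of
    ``log10 freq(k)`` on ``log10 k`` over equal-width connectivity bins.
    Falls back to the argmax R^2 when no candidate reaches the target.
    """
    if table.n_variables < 20:
        raise ValueError("need at least 20 metabolites for topology fitting")
    C = _abs_correlation(table)
    np.fill_diagonal(C, 0.0)
    best_power, best_r2 = None, -np.inf
    for beta in candidate_powers:
        k = (C ** beta).sum(axis=1)
        r2 = _scale_free_r2(k, n_bins)
        if r2 >= target_r2:
            return int(beta)
        if r2 > best_r2:
            best_power, best_r2 = int(beta), r2
    return best_power


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < n_bins:
        return -np.inf
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    freq, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = freq > 0
    if mask.sum() < 3:
        return -np.inf
    x = np.log10(centers[mask])
    y = np.log10(freq[mask] / freq.sum())
    if np.ptp(x) == 0:
        return -np.inf
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbor-weighted similarity of an adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    TOM_ii = 1.
    """
    a = adjacency
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def _gap_cut_height(link: np.ndarray) -> float:
    """Static cut at the largest gap among the upper merge heights.

    TOM dendrograms compress toward 1 as the soft power grows, so a fixed
    height is fragile; the gap between within-module merges and the final
    between-module/noise merges is scale-free. Only the upper half of the
    merge heights is scanned so that early within-module structure cannot
    capture the cut.
    """
    h = np.sort(link[:, 2])
    half = h[h.size // 2:]
    if half.size < 2:
        return float(h[-1]) * 0.5 + 0.5 * float(h[0])
    gaps = np.diff(half)
    i = int(np.argmax(gaps))
    return float((half[i] + half[i + 1]) / 2.0)


def detect_modules(
    table: FeatureTable,
    power: int,
    min_module_size: int = 10,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Cluster metabolites on 1 - TOM; small branches become 'unclustered'.

    With ``cut_height=None`` (default) the static cut is placed in the
    largest gap of the upper merge heights (see :func:`_gap_cut_height`);
    a numeric value forces that height. Module labels are "M1", "M2", ...
    ordered by decreasing module size (ties by first member id) so labels
    are deterministic.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    ids = table.variable_ids
    C = _abs_correlation(table)
    adj = C ** power
    np.fill_diagonal(adj, 0.0)
    tom = tom_similarity(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = average(squareform(dist, checks=False))
    if cut_height is None:
        cut_height = _gap_cut_height(link)
    branch = fcluster(link, t=cut_height, criterion="distance")
    labels: dict[str, str] = {}
    groups: dict[int, list[str]] = {}
    for v, b in zip(ids, branch):
        groups.setdefault(int(b), []).append(v)
    big = [g for g in groups.values() if len(g) >= min_module_size]
    big.sort(key=lambda g: (-len(g), g[0]))
    for rank, g in enumerate(big, start=1):
        for v in g:
            labels[v] = f"M{rank}"
    for g in groups.values():
        if len(g) < min_module_size:
            for v in g:
                labels[v] = UNCLUSTERED
    return ModuleAssignment(labels, soft_power=int(power),
                            min_module_size=min_module_size,
                            cut_height=cut_height)


def module_eigenvalues(
    table: FeatureTable, assignment: ModuleAssignment
) -> tuple[ModuleEigenvalues, FeatureTable]:
    """First-PC summary per module plus the combined downstream table.

    The downstream table concatenates standardized module eigenvalues with
    the (raw) values of unclustered metabolites, matching how module-level
    and singleton features enter later association stages.
    """
    missing = [v for v in table.variable_ids if v not in assignment.labels]
    if missing:
        raise ValueError(f"assignment does not cover variables: {missing[:5]}")
    scores = {}
    var_expl = {}
    n = table.n_samples
    for mod in assignment.module_names:
        members = [v for v in table.variable_ids
                   if assignment.labels[v] == mod]
        if len(members) < 2:
            raise ValueError(f"module {mod} has fewer than 2 members")
        X = table.data[members].to_numpy()
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        # first left singular vector = first PC score of standardized members
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        pc = U[:, 0] * s[0]
        var_expl[mod] = float(s[0] ** 2 / (s ** 2).sum())
        mean_profile = X.mean(axis=1)
        if np.corrcoef(pc, mean_profile)[0, 1] < 0:
            pc = -pc
        pc = (pc - pc.mean()) / pc.std(ddof=1)
        scores[mod] = pc
    ev = ModuleEigenvalues(
        pd.DataFrame(scores, index=table.data.index), var_expl
    )
    unclustered = [v for v in table.variable_ids
                   if assignment.labels[v] == UNCLUSTERED]
    downstream = pd.concat([ev.scores, table.data[unclustered]], axis=1)
    return ev, FeatureTable(downstream, table.variable_meta)
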