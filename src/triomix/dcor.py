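"""Bias-corrected distance correlation and its high-dimensional t-test.

Given two blocks of variables observed on the same samples, the bias-
corrected distance correlation ``r*`` is built from U-centered Euclidean
distance matrices; under independence,

    t = sqrt(v - 1) * r* / sqrt(1 - r*^2),   v = n(n-3)/2,

follows a Student t distribution with v - 1 degrees of freedom, valid even
when the block dimensions exceed the sample size. The test is one-sided
(upper tail): dependence inflates r*.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .containers import CompositionMatrix, FeatureTable

__all__ = ["DcorResult", "u_centered_distances", "dcor_ttest",
           "global_edge_table"]


@dataclass
class DcorResult:
    """Bias-corrected distance correlation t-test between two blocks."""

    r_star: float
    t_stat: float
    dof: int
    p_value: float
    n: int
    block_x: str = "x"
    block_y: str = "y"

    def __repr__(self) -> str:  # compact scientific display
        return (f"DcorResult({self.block_x} ~ {self.block_y}: r*={self.r_star:.4f}, "
                f"t={self.t_stat:.3f}, dof={self.dof}, p={self.p_value:.3g}, "
                f"n={self.n})")


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, FeatureTable):
        x = x.values
    elif isinstance(x, CompositionMatrix):
        x = x.values
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.isnan(x).any():
        raise ValueError("missing values are not supported; drop or impute first")
    return x


def u_centered_distances(x) -> np.ndarray:
    """U-centered Euclidean distance matrix.

    For the pairwise distance matrix ``a`` the U-centered matrix has zero
    diagonal and, for i != j,

        A_ij = a_ij - a_i./(n-2) - a_.j/(n-2) + a_../((n-1)(n-2)),

    where dots denote row/column/grand sums. Every row of the result sums
    to zero exactly (to rounding).
    """
    x = _as_matrix(x)
    n = x.shape[0]
    if n < 4:
        raise ValueError("U-centering needs n >= 4")
    a = squareform(pdist(x, metric="euclidean"))
    row = a.sum(axis=1)
    total = row.sum()
    A = a - row[:, None] / (n - 2) - row[None, :] / (n - 2) \
        + total / ((n - 1) * (n - 2))
    np.fill_diagonal(A, 0.0)
    return A


def _u_inner(A: np.ndarray, B: np.ndarray) -> float:
    # off-diagonal inner product; diagonals are zero by construction
    return float((A * B).sum())


def dcor_ttest(x, y, block_x: str = "x", block_y: str = "y") -> DcorResult:
    """Bias-corrected distance correlation t-test of independence.

    Blocks may have arbitrary (and unequal) numbers of variables; samples
    must be aligned. Errors if either block is degenerate (all samples
    identical), since r* is then undefined.
    """
    X, Y = _as_matrix(x), _as_matrix(y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks are not sample-aligned")
    n = X.shape[0]
    A = u_centered_distances(X)
    B = u_centered_distances(Y)
    aa = _u_inner(A, A)
    bb = _u_inner(B, B)
    if aa <= 0 or bb <= 0:
        raise ValueError("zero-variance block: all samples identical")
    r_star = _u_inner(A, B) / np.sqrt(aa * bb)
    v = n * (n - 3) / 2.0
    dof = int(v - 1)
    r_clip = min(max(r_star, -1.0 + 1e-15), 1.0 - 1e-15)
    t_stat = np.sqrt(v - 1.0) * r_clip / np.sqrt(1.0 - r_clip * r_clip)
    p = float(stats.t.sf(t_stat, dof))
    return DcorResult(float(r_star), float(t_stat), dof, p, n, block_x, block_y)


def _classify(p: float, thick: float = 1e-5, thin: float = 0.1) -> str:
    if p < thick:
        return "thick"
    if p < thin:
        return "thin"
    return "none"


def global_edge_table(blocks: dict[str, object],
                      thick: float = 1e-5, thin: float = 0.1) -> pd.DataFrame:
    """Test every unordered pair of blocks; classify edges by p-value.

    Blocks with differing sample sets are intersected pairwise; the sample
    count used is recorded per row, and pairs with fewer than 10 shared
    samples are flagged ``low_n``. Edge classes mirror the usual network
    display: ``thick`` (p < 1e-5), ``thin`` (1e-5 <= p < 0.1), ``none``.
    """
    if len(blocks) < 2:
        raise ValueError("need at least two blocks")
    rows = []
    for (ni, bi), (nj, bj) in combinations(blocks.items(), 2):
        ids_i = list(bi.sample_ids)
        shared = [s for s in ids_i if s in set(bj.sample_ids)]
        if not shared:
            raise ValueError(f"blocks {ni!r} and {nj!r} share no samples")
        res = dcor_ttest(bi.select_samples(shared), bj.select_samples(shared),
                         block_x=ni, block_y=nj)
        rows.append({
            "block_i": ni, "block_j": nj, "n": res.n, "r_star": res.r_star,
            "t": res.t_stat, "dof": res.dof, "p": res.p_value,
            "edge_class": _classify(res.p_value, thick, thin),
            "low_n": res.n < 10,
        })
    return pd.DataFrame(rows)
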