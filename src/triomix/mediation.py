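"""Compositional mediation of diet effects on metabolites through the microbiome.

For a triplet (dietary variable d, microbial composition X, metabolite y)
the mediator model regresses each coordinate of clr(X) on d (a-path vector
``a``) and the outcome model regresses y on d and the log composition under
the zero-sum constraint on the taxon coefficients (b-path vector ``b`` and
direct effect c'). Because ``b`` sums to zero, b'clr(x) = b'log(x), so the
per-taxon indirect contribution is a_j * b_j and the total indirect effect
is their sum; on linear data total effect = direct + total indirect up to
sampling noise. Uncertainty comes from a joint percentile bootstrap.

Candidate triplets are the diet-metabolite pairs whose stability-selected
genus sets (from the log-contrast stage) share at least one genus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _zerosum
from .containers import CompositionMatrix, FeatureTable
from .logcontrast import LogContrastModel, log_design, top_k_taxa

__all__ = ["MediationResult", "candidate_triplets", "CompositionalMediation",
           "fit_mediation", "mediation_scan"]

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Point estimates and bootstrap CIs for one diet -> taxa -> metabolite triplet."""

    diet_id: str
    metabolite_id: str
    direct_effect: float
    total_indirect: float
    contributions: pd.Series  # per-taxon a_j * b_j
    ci_level: float
    total_ci: tuple[float, float]
    taxon_ci: pd.DataFrame  # columns lower, upper
    n: int
    seed: int | None = None

    @property
    def significant(self) -> bool:
        lo, hi = self.total_ci
        return lo > 0 or hi < 0

    def significant_taxa(self) -> list[str]:
        lo, hi = self.taxon_ci["lower"], self.taxon_ci["upper"]
        return [t for t in self.contributions.index
                if lo[t] > 0 or hi[t] < 0]

    def summary(self) -> str:
        lo, hi = self.total_ci
        lines = [
            f"Compositional mediation: {self.diet_id!r} -> microbiome -> "
            f"{self.metabolite_id!r}  (n={self.n})",
            f"  direct effect   c' = {self.direct_effect:+.4f}",
            f"  total indirect     = {self.total_indirect:+.4f}  "
            f"[{lo:+.4f}, {hi:+.4f}] ({int(self.ci_level*100)}% percentile CI)",
        ]
        for t in self.significant_taxa():
            tlo, thi = self.taxon_ci.loc[t]
            lines.append(f"    {t:<30s} {self.contributions[t]:+.4f} "
                         f"[{tlo:+.4f}, {thi:+.4f}]")
        return "\n".join(lines)


def candidate_triplets(diet_assoc: pd.DataFrame,
                       metab_assoc: pd.DataFrame) -> list[dict]:
    """Diet-metabolite pairs sharing at least one stability-selected genus.

    Both inputs are long association tables from
    :func:`triomix.logcontrast.association_matrix` (columns response, taxon,
    selected).
    """
    def _sets(tab):
        if len(tab) == 0:
            return {}
        sel = tab[tab["selected"]]
        return {r: set(g["taxon"]) for r, g in sel.groupby("response")}

    diet_sets = _sets(diet_assoc)
    metab_sets = _sets(metab_assoc)
    out = []
    for d, gd in diet_sets.items():
        for m, gm in metab_sets.items():
            shared = gd & gm
            if shared:
                out.append({"diet": d, "metabolite": m,
                            "shared_genera": sorted(shared)})
    return out


def _zerosum_outcome(d, Z, y, cv_folds=10, n_lambda=40, seed=0):
    """Outcome model y ~ d + Z with zero-sum constraint on the Z block.

    When the taxon block is smaller than n the fit is exact least squares on
    the KKT system; otherwise the zero-sum lasso at CV-selected lambda picks
    a support which is then refit without penalty (post-selection refit).
    Returns (c_prime, b).
    """
    n, k = Z.shape
    if k + 2 >= n:
        logger.warning("outcome model underdetermined (k=%d, n=%d): "
                       "zero-sum lasso with post-selection refit", k, n)
        # regress out d, select taxa on residual, refit jointly on support
        dd = (d - d.mean())
        r = y - y.mean() - dd * (dd @ (y - y.mean())) / (dd @ dd)
        res = LogContrastModel(r, pd.DataFrame(Z)).fit_cv(
            folds=cv_folds, n_lambda=n_lambda, seed=seed)
        sup = [int(t[1:]) for t in res.support]
        if len(sup) < 2:
            sup = list(range(min(2, k)))
        b = np.zeros(k)
        cp, bs = _exact_outcome(d, Z[:, sup], y)
        b[sup] = bs
        return cp, b
    return _exact_outcome(d, Z, y)


def _exact_outcome(d, Z, y):
    """Least squares of y on [1, d, Z] with sum(b_Z) = 0, via bordered KKT."""
    n, k = Z.shape
    X = np.column_stack([np.ones(n), d, Z])
    p = k + 2
    K = np.zeros((p + 1, p + 1))
    K[:p, :p] = X.T @ X
    K[2:p, p] = 1.0  # constraint touches only taxon coefficients
    K[p, 2:p] = 1.0
    rhs = np.concatenate([X.T @ y, [0.0]])
    sol = np.linalg.solve(K, rhs)
    return float(sol[1]), sol[2:p]


def _paths(d, clrX, Z, y, cv_folds, n_lambda, seed):
    dd = d - d.mean()
    denom = dd @ dd
    if denom == 0:
        raise ValueError("constant diet variable")
    a = (clrX - clrX.mean(axis=0)).T @ dd / denom
    c_prime, b = _zerosum_outcome(d, Z, y, cv_folds, n_lambda, seed)
    return a, b, c_prime


class CompositionalMediation:
    """Mediation model for one diet variable, a composition, and one metabolite.

    Parameters
    ----------
    diet : array-like
        Exposure vector (standardized dietary variable).
    composition : CompositionMatrix or pandas.DataFrame
        Candidate mediators (top-k genera); zeros handled by the
        multiplicative replacement of :func:`triomix.logcontrast.log_design`.
    outcome : array-like
        Metabolite vector.
    covariates : array-like, optional
        n x c matrix residualized out of diet, log-composition, and outcome
        before fitting (confounding control).
    """

    def __init__(self, diet, composition, outcome, covariates=None,
                 diet_id: str = "diet", metabolite_id: str = "metabolite"):
        self.diet_id, self.metabolite_id = diet_id, metabolite_id
        d = np.asarray(diet, dtype=float).ravel()
        y = np.asarray(outcome, dtype=float).ravel()
        if isinstance(composition, CompositionMatrix):
            Zdf = log_design(composition)
        elif isinstance(composition, pd.DataFrame):
            Zdf = composition
        else:
            Zdf = pd.DataFrame(np.asarray(composition, dtype=float))
        self.taxon_ids = list(Zdf.columns)
        Z = Zdf.to_numpy(dtype=float)
        if not (len(d) == len(y) == Z.shape[0]):
            raise ValueError("diet, composition and outcome are not aligned")
        if np.ptp(d) == 0:
            raise ValueError("constant diet variable")
        if covariates is not None:
            C = np.column_stack([np.ones(len(d)),
                                 np.asarray(covariates, dtype=float)])
            proj = C @ np.linalg.lstsq(C, np.column_stack([d, y, Z]),
                                       rcond=None)[0]
            d = d - proj[:, 0]
            y = y - proj[:, 1]
            Z = Z - proj[:, 2:]
        self.d, self.y, self.Z = d, y, Z
        self.clrX = Z - Z.mean(axis=1, keepdims=True)

    def fit(self, n_bootstrap: int = 500, ci_level: float = 0.95,
            seed: int = 0, cv_folds: int = 10,
            n_lambda: int = 40) -> MediationResult:
        """Point estimates plus joint percentile-bootstrap confidence intervals."""
        n = len(self.d)
        a, b, c_prime = _paths(self.d, self.clrX, self.Z, self.y,
                               cv_folds, n_lambda, seed)
        contrib = a * b
        rng = np.random.default_rng(seed)
        boot_total = np.empty(n_bootstrap)
        boot_taxa = np.empty((n_bootstrap, len(b)))
        for i in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            db = self.d[idx]
            if np.ptp(db) == 0:
                boot_total[i] = np.nan
                boot_taxa[i] = np.nan
                continue
            ab, bb, _ = _paths(db, self.clrX[idx], self.Z[idx], self.y[idx],
                               cv_folds, n_lambda,
                               int(rng.integers(2 ** 31)))
            boot_taxa[i] = ab * bb
            boot_total[i] = boot_taxa[i].sum()
        alpha = 1.0 - ci_level
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        tot_lo, tot_hi = np.nanpercentile(boot_total, qs)
        tax_lo, tax_hi = np.nanpercentile(boot_taxa, qs, axis=0)
        return MediationResult(
            diet_id=self.diet_id, metabolite_id=self.metabolite_id,
            direct_effect=c_prime, total_indirect=float(contrib.sum()),
            contributions=pd.Series(contrib, index=self.taxon_ids),
            ci_level=ci_level, total_ci=(float(tot_lo), float(tot_hi)),
            taxon_ci=pd.DataFrame({"lower": tax_lo, "upper": tax_hi},
                                  index=self.taxon_ids),
            n=n, seed=seed,
        )


def fit_mediation(diet, Z, y, n_bootstrap: int = 500, ci_level: float = 0.95,
                  seed: int = 0, diet_id: str = "diet",
                  metabolite_id: str = "metabolite") -> MediationResult:
    """Functional wrapper around :class:`CompositionalMediation`."""
    return CompositionalMediation(
        diet, Z, y, diet_id=diet_id, metabolite_id=metabolite_id
    ).fit(n_bootstrap=n_bootstrap, ci_level=ci_level, seed=seed)


def mediation_scan(triplets, composition: CompositionMatrix,
                   diet_table: FeatureTable, metab_table: FeatureTable,
                   k: int = 50, n_bootstrap: int = 500,
                   ci_level: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Run mediation over every candidate triplet; flag CI-excluding-zero rows.

    Returns one row per triplet with the total indirect effect, its CI, the
    direct effect, the significance flag, and the comma-joined taxa whose
    per-taxon CIs exclude zero. Per-triplet failures are logged, not fatal.
    """
    comp = top_k_taxa(composition, k) if k < composition.n_taxa else composition
    Z = log_design(comp)
    rows = []
    for i, trip in enumerate(triplets):
        d_id, m_id = trip["diet"], trip["metabolite"]
        try:
            res = CompositionalMediation(
                diet_table.data[d_id].to_numpy(), Z,
                metab_table.data[m_id].to_numpy(),
                diet_id=d_id, metabolite_id=m_id,
            ).fit(n_bootstrap=n_bootstrap, ci_level=ci_level,
                  seed=(seed + 1009 * i) % (2 ** 31))
        except Exception as exc:
            logger.error("triplet (%s, %s) failed: %s", d_id, m_id, exc)
            continue
        rows.append({
            "diet": d_id, "metabolite": m_id,
            "direct_effect": res.direct_effect,
            "total_indirect": res.total_indirect,
            "ci_lower": res.total_ci[0], "ci_upper": res.total_ci[1],
            "significant": res.significant,
            "mediating_taxa": ",".join(res.significant_taxa()),
            "n": res.n,
        })
    cols = ["diet", "metabolite", "direct_effect", "total_indirect",
            "ci_lower", "ci_upper", "significant", "mediating_taxa", "n"]
    return pd.DataFrame(rows, columns=cols)
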