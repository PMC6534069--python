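"""Sparse linear log-contrast regression with bootstrap stability selection.

The model regresses a (preprocessed) dietary or metabolite variable on the
log relative abundances of the top-k genera under the zero-sum constraint
``sum_j beta_j = 0``, which the unit-sum constraint of the composition
induces on the coefficients and which makes fits invariant to per-sample
rescaling of counts. The penalty is tuned by 10-fold cross-validation
(minimum mean squared error); selection is stabilized by refitting on 100
bootstrap resamples and declaring a genus associated only when it enters
the selected model in strictly more than 70 of them.

The public surface follows the statsmodels idiom: build a
:class:`LogContrastModel` from a response and a composition (or a
pre-built log design), call :meth:`fit`/:meth:`fit_cv`, and read the
estimates off the returned :class:`LogContrastResults`.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _zerosum
from .containers import CompositionMatrix, FeatureTable

__all__ = [
    "top_k_taxa",
    "log_design",
    "LogContrastModel",
    "LogContrastResults",
    "SelectionProfile",
    "fit_log_contrast",
    "cv_select_lambda",
    "stability_select",
    "association_matrix",
]

logger = logging.getLogger(__name__)

ZERO_SUM_TOL = 1e-8


def top_k_taxa(composition: CompositionMatrix, k: int = 50) -> CompositionMatrix:
    """Keep the k genera with the highest mean relative abundance; re-close.

    Ties at the k-th rank are broken deterministically by taxon id (and
    logged). Raw counts, if present, are subset alongside but not re-closed.
    """
    if k > composition.n_taxa:
        raise ValueError(f"k={k} exceeds {composition.n_taxa} taxa")
    means = composition.proportions.mean(axis=0)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    if k < composition.n_taxa and means[order[k - 1]] == means[order[k]]:
        logger.info("tie at rank %d broken by taxon id", k)
    keep = [t for t in composition.taxon_ids if t in set(order[:k])]
    sub = composition.proportions[keep]
    sub = sub.div(sub.sum(axis=1), axis=0)
    counts = composition.counts[keep] if composition.counts is not None else None
    return CompositionMatrix(sub, counts)


def log_design(composition: CompositionMatrix,
               pseudo: str = "half-min") -> pd.DataFrame:
    """Log-transform a composition after multiplicative zero replacement.

    Zeros are replaced by delta = half the smallest nonzero proportion in
    the matrix; the nonzero entries of each row are scaled down by
    ``(1 - z_i * delta)`` (z_i = number of zeros in row i) so the row still
    sums to one, then the elementwise log is taken.
    """
    if pseudo != "half-min":
        raise ValueError(f"unknown zero-replacement rule {pseudo!r}")
    P = composition.values
    if (P.sum(axis=1) == 0).any():
        raise ValueError("row of all zeros")
    nonzero = P[P > 0]
    if nonzero.size == P.size:
        Z = np.log(P)
    else:
        delta = nonzero.min() / 2.0
        z_per_row = (P == 0).sum(axis=1)
        if (z_per_row * delta >= 1.0).any():
            raise ValueError("too many zeros for multiplicative replacement")
        scale = (1.0 - z_per_row * delta) / P.sum(axis=1)
        R = P * scale[:, None]
        R[P == 0] = delta
        Z = np.log(R)
    return pd.DataFrame(Z, index=composition.proportions.index,
                        columns=composition.proportions.columns)


@dataclass
class LogContrastResults:
    """Estimates from a zero-sum log-contrast fit.

    ``beta`` always sums to zero (within 1e-8); when the fit came from
    :meth:`LogContrastModel.fit_cv`, the regularization path and CV curves
    are attached.
    """

    beta: pd.Series
    intercept: float
    lam: float
    response_id: str = "y"
    lambda_grid: np.ndarray | None = None
    path: np.ndarray | None = None  # len(grid) x k coefficients
    cv_mean_error: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    lambda_selected: float | None = None
    seed: int | None = None
    kkt: float = np.nan

    @property
    def support(self) -> list[str]:
        return [t for t, b in self.beta.items() if abs(b) > 1e-10]

    def predict(self, Z: pd.DataFrame | np.ndarray) -> np.ndarray:
        Zv = Z.to_numpy() if hasattr(Z, "to_numpy") else np.asarray(Z)
        return self.intercept + Zv @ self.beta.to_numpy()

    def summary(self) -> str:
        lines = [
            f"Zero-sum log-contrast fit: response {self.response_id!r}",
            f"  n taxa: {len(self.beta)}   lambda: {self.lam:.6g}"
            + (f" (CV-selected from {len(self.lambda_grid)} grid points)"
               if self.lambda_selected is not None else ""),
            f"  sum(beta) = {self.beta.sum():.2e}   KKT residual = {self.kkt:.2e}",
            f"  support size: {len(self.support)}",
        ]
        for t in self.support:
            lines.append(f"    {t:<30s} {self.beta[t]:+.4f}")
        return "\n".join(lines)


class LogContrastModel:
    """Zero-sum constrained lasso of a response on log relative abundances.

    Parameters
    ----------
    y : array-like or pandas.Series
        Response (a preprocessed diet or metabolite variable).
    Z : pandas.DataFrame
        n x k log-design from :func:`log_design` (columns = taxa).
    """

    def __init__(self, y, Z: pd.DataFrame, response_id: str = "y"):
        self.y = np.asarray(y, dtype=float).ravel()
        if isinstance(Z, pd.DataFrame):
            self.taxon_ids = list(Z.columns)
            self.Z = Z.to_numpy(dtype=float)
        else:
            self.Z = np.asarray(Z, dtype=float)
            self.taxon_ids = [f"t{j}" for j in range(self.Z.shape[1])]
        if self.Z.shape[0] != self.y.shape[0]:
            raise ValueError("y and Z are not sample-aligned")
        if np.isnan(self.y).any() or np.isnan(self.Z).any():
            raise ValueError("missing values are not supported")
        self.response_id = response_id

    @classmethod
    def from_composition(cls, y, composition: CompositionMatrix,
                         k: int | None = 50, response_id: str = "y"):
        comp = top_k_taxa(composition, k) if k is not None else composition
        return cls(y, log_design(comp), response_id=response_id)

    # -- sufficient statistics on (sub)samples ---------------------------
    def _stats(self, idx=None):
        Z = self.Z if idx is None else self.Z[idx]
        y = self.y if idx is None else self.y[idx]
        zbar = Z.mean(axis=0)
        ybar = y.mean()
        Zc = Z - zbar
        yc = y - ybar
        n = Z.shape[0]
        return Zc.T @ Zc / n, Zc.T @ yc / n, zbar, ybar

    def fit(self, lam: float) -> LogContrastResults:
        """Solve at a single penalty value."""
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        Q, q, zbar, ybar = self._stats()
        if lam == 0.0:
            beta = _zerosum.constrained_ls(Q, q)
        else:
            beta, _ = _zerosum.solve_zerosum(Q, q, lam)
        kkt = _zerosum.kkt_residual(Q, q, lam, beta)
        if kkt > 1e-6:
            raise RuntimeError(f"solver did not converge: KKT residual {kkt:.2e}")
        return LogContrastResults(
            beta=pd.Series(beta, index=self.taxon_ids),
            intercept=float(ybar - zbar @ beta),
            lam=float(lam), response_id=self.response_id, kkt=kkt,
        )

    def lambda_grid(self, n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
        _, q, _, _ = self._stats()
        lmax = _zerosum.lambda_max(q)
        if lmax <= 0:
            lmax = 1e-8
        return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambda)

    def fit_cv(self, folds: int = 10, n_lambda: int = 100, seed: int = 0,
               lambda_grid: np.ndarray | None = None) -> LogContrastResults:
        """Tune lambda by k-fold CV (minimum mean squared error rule).

        Fold assignment is a seeded permutation, so the same seed always
        yields the same folds and the same selected lambda.
        """
        grid = (np.asarray(lambda_grid, dtype=float) if lambda_grid is not None
                else self.lambda_grid(n_lambda))
        beta, intercept, lam_sel, cv_mean, cv_se, path, kkt = _cv_core(
            self.Z, self.y, folds, grid, seed
        )
        return LogContrastResults(
            beta=pd.Series(beta, index=self.taxon_ids),
            intercept=intercept,
            lam=lam_sel, response_id=self.response_id,
            lambda_grid=grid, path=path,
            cv_mean_error=cv_mean, cv_se=cv_se,
            lambda_selected=lam_sel, seed=seed, kkt=kkt,
        )


def _cv_core(Z: np.ndarray, y: np.ndarray, folds: int, grid: np.ndarray,
             seed: int, groups: np.ndarray | None = None):
    """Array-level CV engine shared by fit_cv and stability selection.

    ``groups`` assigns rows to fold-atomic units: rows sharing a group id
    are never split between training and validation. Bootstrap replicates
    use this with the original sample index as the group, so duplicated
    draws of one subject cannot leak across the fold boundary.
    """
    n = y.shape[0]
    if n < folds:
        raise ValueError("more folds than samples")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = np.arange(n)
    uniq = np.unique(groups)
    perm = rng.permutation(uniq.size)
    group_fold = np.empty(uniq.size, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        if chunk.size < 1:
            raise ValueError("fold with no groups")
        group_fold[chunk] = f
    pos = {g: i for i, g in enumerate(uniq)}
    fold_of = np.array([group_fold[pos[g]] for g in groups])
    if min(np.bincount(fold_of, minlength=folds)) < 2:
        raise ValueError("fold with fewer than 2 samples")
    errs = np.empty((folds, grid.size))
    for f in range(folds):
        tr = fold_of != f
        te = ~tr
        Ztr, ytr = Z[tr], y[tr]
        zbar, ybar = Ztr.mean(axis=0), ytr.mean()
        Zc, yc = Ztr - zbar, ytr - ybar
        m = Ztr.shape[0]
        path = _zerosum.solve_path(Zc.T @ Zc / m, Zc.T @ yc / m, grid)
        pred = ybar + (Z[te] - zbar) @ path.T  # n_test x L
        errs[f] = ((y[te, None] - pred) ** 2).mean(axis=0)
    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(cv_mean))  # grid descends: first min = sparsest
    lam_sel = float(grid[best])
    zbar, ybar = Z.mean(axis=0), y.mean()
    Zc, yc = Z - zbar, y - ybar
    Q, q = Zc.T @ Zc / n, Zc.T @ yc / n
    path = _zerosum.solve_path(Q, q, grid)
    beta = path[best]
    kkt = _zerosum.kkt_residual(Q, q, lam_sel, beta)
    return beta, float(ybar - zbar @ beta), lam_sel, cv_mean, cv_se, path, kkt


def fit_log_contrast(Z: pd.DataFrame, y, lam: float,
                     response_id: str = "y") -> LogContrastResults:
    """Single-penalty fit of the zero-sum lasso (functional form)."""
    return LogContrastModel(y, Z, response_id=response_id).fit(lam)


def cv_select_lambda(Z: pd.DataFrame, y, folds: int = 10,
                     lambda_grid: np.ndarray | None = None,
                     n_lambda: int = 100, seed: int = 0,
                     response_id: str = "y") -> LogContrastResults:
    """CV-tuned fit of the zero-sum lasso (functional form)."""
    return LogContrastModel(y, Z, response_id=response_id).fit_cv(
        folds=folds, n_lambda=n_lambda, seed=seed, lambda_grid=lambda_grid
    )


@dataclass
class SelectionProfile:
    """Bootstrap selection frequencies for one response."""

    response_id: str
    selection_count: pd.Series  # per taxon, out of n_bootstrap
    n_bootstrap: int
    threshold: int
    mean_coefficient: pd.Series  # mean over replicates where nonzero
    n_skipped: int = 0

    @property
    def selected(self) -> list[str]:
        return [t for t, c in self.selection_count.items()
                if c > self.threshold]

    @property
    def signs(self) -> pd.Series:
        return np.sign(self.mean_coefficient)


def stability_select(Z: pd.DataFrame, y, n_bootstrap: int = 100,
                     threshold: int = 70, folds: int = 10,
                     n_lambda: int = 100, seed: int = 0,
                     response_id: str = "y") -> SelectionProfile:
    """Bootstrap stability selection around the CV-tuned zero-sum lasso.

    Each replicate resamples the n samples with replacement, re-runs the
    full CV tuning on the resample, and records the support of the selected
    model. A genus is declared associated when its count exceeds
    ``threshold`` (strictly). Replicates with a constant resampled response
    are skipped and logged; the denominator stays ``n_bootstrap``.
    """
    model = LogContrastModel(y, Z, response_id=response_id)
    n, k = model.Z.shape
    grid = model.lambda_grid(n_lambda)
    rng = np.random.default_rng(seed)
    counts = np.zeros(k, dtype=int)
    coef_sum = np.zeros(k)
    coef_n = np.zeros(k, dtype=int)
    n_skipped = 0
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        yb = model.y[idx]
        if np.ptp(yb) == 0:
            n_skipped += 1
            logger.warning("bootstrap replicate %d: constant response, skipped", b)
            continue
        beta, *_ = _cv_core(model.Z[idx], yb, folds, grid,
                            int(rng.integers(2 ** 31)), groups=idx)
        nz = np.abs(beta) > 1e-10
        counts += nz
        coef_sum += np.where(nz, beta, 0.0)
        coef_n += nz
    with np.errstate(invalid="ignore"):
        mean_coef = np.where(coef_n > 0, coef_sum / np.maximum(coef_n, 1), 0.0)
    return SelectionProfile(
        response_id=response_id,
        selection_count=pd.Series(counts, index=model.taxon_ids),
        n_bootstrap=n_bootstrap, threshold=threshold,
        mean_coefficient=pd.Series(mean_coef, index=model.taxon_ids),
        n_skipped=n_skipped,
    )


def _response_seed(master_seed: int, response_id: str) -> int:
    return (int(master_seed) + zlib.crc32(response_id.encode())) % (2 ** 31)


def association_matrix(responses: FeatureTable, composition: CompositionMatrix,
                       k: int = 50, n_bootstrap: int = 100, threshold: int = 70,
                       folds: int = 10, n_lambda: int = 100,
                       seed: int = 0) -> pd.DataFrame:
    """Stability-select genera for every response; emit a long association table.

    Per-response seeds are derived deterministically from the master seed
    and the response id, so a response gives identical results regardless
    of which other responses are scanned alongside it. Failures on a single
    response are logged and skipped, not fatal.

    Returns a DataFrame with columns response, taxon, selection_count,
    mean_coefficient, selected.
    """
    comp = top_k_taxa(composition, k) if k < composition.n_taxa else composition
    Z = log_design(comp)
    rows = []
    for rid in responses.variable_ids:
        y = responses.data[rid].to_numpy()
        try:
            prof = stability_select(
                Z, y, n_bootstrap=n_bootstrap, threshold=threshold,
                folds=folds, n_lambda=n_lambda,
                seed=_response_seed(seed, rid), response_id=rid,
            )
        except Exception as exc:  # pragma: no cover - defensive per-response
            logger.error("response %r failed: %s", rid, exc)
            continue
        for t in Z.columns:
            c = int(prof.selection_count[t])
            if c > 0:
                rows.append({
                    "response": rid, "taxon": t, "selection_count": c,
                    "mean_coefficient": float(prof.mean_coefficient[t]),
                    "selected": c > threshold,
                })
    cols = ["response", "taxon", "selection_count", "mean_coefficient",
            "selected"]
    return pd.DataFrame(rows, columns=cols)
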