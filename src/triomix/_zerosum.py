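"""Numerical kernels for the zero-sum constrained lasso.

Solves, for centered response y and centered log-abundance design Z,

    minimize (1/2n) ||y - Z beta||^2 + lambda ||beta||_1
    subject to  sum_j beta_j = 0,

by dualizing the equality constraint: for a multiplier nu the inner problem
is an ordinary lasso with shifted linear term q - nu, solved by Gram-matrix
coordinate descent; the constraint gap s(nu) = sum_j beta_j(nu) is monotone
non-increasing and piecewise linear in nu, so a safeguarded secant /
bisection drives it to zero in a handful of warm-started inner solves.
Inner convergence is certified against the lasso stationarity conditions,
not just coordinate-move size. The gradient vector Q beta is maintained
incrementally, so a sweep costs O(k) plus O(k) per coordinate that actually
moves.

All kernels take the sufficient statistics Q = Z'Z/n and q = Z'y/n; the
per-update cost is independent of the sample size n.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lambda_max", "solve_zerosum", "solve_path", "kkt_residual",
           "constrained_ls"]


def lambda_max(q: np.ndarray) -> float:
    """Smallest penalty at which beta = 0 is optimal.

    beta = 0 is stationary iff some multiplier nu satisfies
    |q_j - nu| <= lambda for all j; the minimal such lambda is
    (max q - min q)/2.
    """
    return float((q.max() - q.min()) / 2.0)


@njit(cache=True)
def _sweep(Q, q, nu, lam, beta, grad, active_only, active):
    """One coordinate sweep; ``grad`` holds Q beta and is kept current."""
    k = q.shape[0]
    max_delta = 0.0
    for j in range(k):
        if active_only and not active[j]:
            continue
        denom = Q[j, j]
        if denom <= 0.0:
            continue
        r = q[j] - nu - (grad[j] - denom * beta[j])
        if r > lam:
            new = (r - lam) / denom
        elif r < -lam:
            new = (r + lam) / denom
        else:
            new = 0.0
        d = new - beta[j]
        if d != 0.0:
            beta[j] = new
            active[j] = new != 0.0
            for l in range(k):
                grad[l] += Q[l, j] * d
            if abs(d) > max_delta:
                max_delta = abs(d)
    return max_delta


@njit(cache=True)
def _subproblem_kkt(Q, q, nu, lam, beta, grad):
    """Stationarity violation of the nu-shifted lasso (O(k) with grad)."""
    k = q.shape[0]
    viol = 0.0
    for j in range(k):
        g = grad[j] - q[j] + nu
        if beta[j] > 1e-12:
            v = abs(g + lam)
        elif beta[j] < -1e-12:
            v = abs(g - lam)
        else:
            v = abs(g) - lam
            if v < 0.0:
                v = 0.0
        if v > viol:
            viol = v
    return viol


@njit(cache=True)
def _lasso(Q, q, nu, lam, beta, grad, active, tol, kkt_tol, max_sweeps):
    """Solve the nu-shifted lasso toward certified stationarity.

    ``max_sweeps`` is a TOTAL sweep budget (full + active-set): on flat
    problems (rank-deficient Q, non-unique minimizer) certification may be
    unattainable and the best effort within budget is returned; the caller
    re-certifies through the exact polish. Returns sum(beta).
    """
    total = 0
    while total < max_sweeps:
        delta = _sweep(Q, q, nu, lam, beta, grad, False, active)
        total += 1
        while delta > tol and total < max_sweeps:
            delta = _sweep(Q, q, nu, lam, beta, grad, True, active)
            total += 1
        if _subproblem_kkt(Q, q, nu, lam, beta, grad) <= kkt_tol:
            break
    s = 0.0
    for j in range(q.shape[0]):
        s += beta[j]
    return s


@njit(cache=True)
def _polish(Q, q, lam, beta, grad):
    """Active-set KKT polish: exact solve on the support found by CD.

    Given a near-solution, solve the equality-constrained quadratic
    restricted to the active coordinates with their signs fixed,

        [[Q_AA, 1], [1', 0]] [beta_A; nu] = [q_A - lam*sign_A; 0],

    dropping coordinates whose solved sign flips and admitting inactive
    coordinates that violate |grad_j - q_j + nu| <= lam, until the full KKT
    system holds to ~1e-10. Returns 1 on success, 0 if the active-set loop
    failed to settle (caller falls back to more CD).
    """
    k = q.shape[0]
    act = np.zeros(k, dtype=np.bool_)
    sgn = np.zeros(k)
    for j in range(k):
        if beta[j] != 0.0:
            act[j] = True
            sgn[j] = 1.0 if beta[j] > 0.0 else -1.0
    for _ in range(4 * k):
        idx = np.flatnonzero(act)
        na = idx.shape[0]
        if na == 0:
            # beta = 0 candidate: feasible iff some nu fits all margins
            lo_n = -1e300
            hi_n = 1e300
            for j in range(k):
                if q[j] - lam > lo_n:
                    lo_n = q[j] - lam
                if q[j] + lam < hi_n:
                    hi_n = q[j] + lam
            if lo_n <= hi_n + 1e-12:
                for j in range(k):
                    beta[j] = 0.0
                    grad[j] = 0.0
                return 1
            # admit the most violating coordinate
            best_j, best_v = -1, -1.0
            for j in range(k):
                v = abs(q[j]) - lam
                if v > best_v:
                    best_v, best_j = v, j
            act[best_j] = True
            sgn[best_j] = 1.0 if q[best_j] > 0.0 else -1.0
            continue
        K = np.zeros((na + 1, na + 1))
        rhs = np.zeros(na + 1)
        for a in range(na):
            for b in range(na):
                K[a, b] = Q[idx[a], idx[b]]
            K[a, a] += 1e-11 * (1.0 + Q[idx[a], idx[a]])  # ridge for rank-deficient active sets
            K[a, na] = 1.0
            K[na, a] = 1.0
            rhs[a] = q[idx[a]] - lam * sgn[idx[a]]
        sol = np.linalg.solve(K, rhs)
        nu = sol[na]
        # drop only the worst sign violation (anti-cycling on flat problems)
        worst_a, worst_v = -1, 0.0
        for a in range(na):
            v = -sol[a] * sgn[idx[a]]
            if v > worst_v:
                worst_v, worst_a = v, a
        if worst_a >= 0:
            act[idx[worst_a]] = False
            continue
        newb = np.zeros(k)
        for a in range(na):
            newb[idx[a]] = sol[a]
        newg = Q @ newb
        # check inactive margins; admit worst violator
        best_j, best_v = -1, 1e-10
        for j in range(k):
            if act[j]:
                continue
            v = abs(newg[j] - q[j] + nu) - lam
            if v > best_v:
                best_v, best_j = v, j
        if best_j >= 0:
            act[best_j] = True
            sgn[best_j] = 1.0 if (q[best_j] - newg[best_j] - nu) > 0.0 else -1.0
            for j in range(k):
                beta[j] = newb[j]
                grad[j] = newg[j]
            continue
        for j in range(k):
            beta[j] = newb[j]
            grad[j] = newg[j]
        return 1
    return 0


@njit(cache=True)
def _solve_cd(Q, q, lam, beta, grad, nu0, tol, kkt_tol, s_tol, max_sweeps,
              max_nu_iter):
    """Root-find nu so that sum(beta(nu)) = 0. Returns final nu."""
    k = q.shape[0]
    active = np.zeros(k, dtype=np.bool_)
    for j in range(k):
        active[j] = beta[j] != 0.0
    avg_diag = 0.0
    for j in range(k):
        avg_diag += Q[j, j]
    avg_diag /= k
    nu = nu0
    s = _lasso(Q, q, nu, lam, beta, grad, active, tol, kkt_tol, max_sweeps)
    if abs(s) < s_tol:
        return nu
    m = 1.0
    for j in range(k):
        if active[j]:
            m += 1.0
    slope = -m / avg_diag  # initial secant slope guess
    lo = -1e300  # nu with s(lo) > 0
    hi = 1e300   # nu with s(hi) < 0
    if s > 0.0:
        lo = nu
    else:
        hi = nu
    nu_prev, s_prev = nu, s
    nu = nu - s / slope
    for _ in range(max_nu_iter):
        if lo > -1e300 and hi < 1e300 and (nu <= lo or nu >= hi):
            nu = 0.5 * (lo + hi)
        s = _lasso(Q, q, nu, lam, beta, grad, active, tol, kkt_tol, max_sweeps)
        if abs(s) < s_tol:
            return nu
        if s > 0.0:
            if nu > lo:
                lo = nu
        else:
            if nu < hi:
                hi = nu
        if s != s_prev and nu != nu_prev:
            slope = (s - s_prev) / (nu - nu_prev)
            if slope >= 0.0:  # numerical tie; fall back to bisection scale
                slope = -m / avg_diag
        nu_prev, s_prev = nu, s
        nu = nu - s / slope
    return nu


@njit(cache=True)
def _solve_one(Q, q, lam, beta, grad, nu0, tol, kkt_tol, s_tol, max_sweeps,
               max_nu_iter):
    """Loose CD root-find to identify the support, then exact KKT polish.

    Falls back to a tight CD solve in the (rare) case the active-set polish
    cycles. Returns the final nu.
    """
    nu = _solve_cd(Q, q, lam, beta, grad, nu0, tol, kkt_tol, s_tol,
                   max_sweeps, max_nu_iter)
    if _polish(Q, q, lam, beta, grad) == 0:
        # rare: re-run CD at tighter (but still bounded) effort, re-polish
        nu = _solve_cd(Q, q, lam, beta, grad, nu, 1e-8, 1e-7, 1e-8,
                       max_sweeps, max_nu_iter)
        _polish(Q, q, lam, beta, grad)
    return nu


def solve_zerosum(Q, q, lam, beta0=None, nu0=0.0,
                  tol=1e-4, kkt_tol=1e-3, s_tol=1e-2, max_sweeps=500,
                  max_nu_iter=50):
    """Solve one penalized problem; returns (beta, dual nu)."""
    Q = np.ascontiguousarray(Q, dtype=np.float64)
    k = q.shape[0]
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, float).copy()
    grad = Q @ beta
    nu = _solve_one(Q, np.ascontiguousarray(q, dtype=np.float64),
                    float(lam), beta, grad, float(nu0),
                    tol, kkt_tol, s_tol, max_sweeps, max_nu_iter)
    return beta, nu


@njit(cache=True)
def _path_kernel(Q, q, lambdas, tol, kkt_tol, s_tol, max_sweeps, max_nu_iter):
    k = q.shape[0]
    L = lambdas.shape[0]
    betas = np.zeros((L, k))
    beta = np.zeros(k)
    grad = np.zeros(k)
    nu = 0.0
    for i in range(L):
        nu = _solve_one(Q, q, lambdas[i], beta, grad, nu,
                        tol, kkt_tol, s_tol, max_sweeps, max_nu_iter)
        for j in range(k):
            betas[i, j] = beta[j]
    return betas


def solve_path(Q, q, lambdas, tol=1e-4, kkt_tol=1e-3, s_tol=1e-2,
               max_sweeps=500, max_nu_iter=50):
    """Warm-started solution path over a decreasing lambda grid."""
    return _path_kernel(np.ascontiguousarray(Q, dtype=np.float64),
                        np.ascontiguousarray(q, dtype=np.float64),
                        np.ascontiguousarray(lambdas, dtype=np.float64),
                        tol, kkt_tol, s_tol, max_sweeps, max_nu_iter)


def kkt_residual(Q, q, lam, beta) -> float:
    """Max violation of the stationarity conditions of the constrained lasso.

    With gradient g = Q beta - q, optimality requires a multiplier nu with
    g_j + nu = -lam * sign(beta_j) on the active set and |g_j + nu| <= lam
    elsewhere. The multiplier is profiled out from the active coordinates.
    Also folds in the constraint violation |sum beta|.
    """
    g = Q @ beta - q
    active = np.abs(beta) > 1e-10
    if active.any():
        nu = float(np.mean(-g[active] - lam * np.sign(beta[active])))
    else:
        nu = float(-(g.max() + g.min()) / 2.0)
    viol = 0.0
    for j in range(beta.shape[0]):
        gj = g[j] + nu
        if active[j]:
            viol = max(viol, abs(gj + lam * np.sign(beta[j])))
        else:
            viol = max(viol, max(0.0, abs(gj) - lam))
    viol = max(viol, abs(beta.sum()))
    return viol


def constrained_ls(Q, q):
    """Closed-form zero-sum least squares (lambda = 0) via the KKT system.

    Solves [[Q, 1], [1', 0]] [beta; nu] = [q; 0]. Requires Q nonsingular on
    the constraint subspace (k < n and no exact collinearity).
    """
    k = q.shape[0]
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = Q
    K[:k, k] = 1.0
    K[k, :k] = 1.0
    rhs = np.concatenate([q, [0.0]])
    sol = np.linalg.solve(K, rhs)
    return sol[:k]
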