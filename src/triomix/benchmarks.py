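"""Self-contained benchmark runs exercising every stage on planted truth.

Each function simulates its own inputs from an explicit seed, runs the
relevant pipeline stage, and returns the measured quantities (calibration
rates, recovery sensitivities, agreement with closed forms). They are the
single source for both the acceptance test suite and the standalone
acceptance script, so the reported numbers always come from a fresh
computation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import _zerosum
from .dcor import dcor_ttest
from .enterotype import (_ols_interaction, choose_enterotypes,
                         enterotype_characterize, pam_cluster)
from .logcontrast import LogContrastModel, log_design, stability_select, \
    top_k_taxa
from .mediation import CompositionalMediation
from .modules import detect_modules, module_eigenvalues, soft_threshold_power
from .preprocess import int_table, preprocess_diet, shapiro_screen
from .simulate import (simulate_diet, simulate_mediation_benchmark,
                       simulate_microbiome, simulate_study)

__all__ = [
    "dcor_calibration", "dcor_oracle_agreement", "u_centering_identity",
    "logcontrast_exactness", "stability_recovery", "mediation_recovery",
    "pam_optimality", "enterotype_recovery", "module_recovery",
    "interaction_calibration_power", "preprocess_chain",
]

# fixed detectable zero-sum pattern for the planted-effect benchmarks
EFFECT_PATTERN = np.array([1.0, -1.0, 0.8, -0.5, -0.3])


def dcor_calibration(n: int = 30, p: int = 10, q: int = 10,
                     reps: int = 2000, alpha: float = 0.05,
                     seed: int = 0) -> dict:
    """Type-I error of the dcor t-test on independent Gaussian blocks."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(reps):
        x = rng.normal(size=(n, p))
        y = rng.normal(size=(n, q))
        rej += dcor_ttest(x, y).p_value < alpha
    return {"rejection_rate": rej / reps, "n": reps}


def _brute_force_rstar(x, y):
    def dmat(z):
        return np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(-1))

    def ucenter(a):
        n = a.shape[0]
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    A[i, j] = (a[i, j] - a[i, :].sum() / (n - 2)
                               - a[:, j].sum() / (n - 2)
                               + a.sum() / ((n - 1) * (n - 2)))
        return A

    A, B = ucenter(dmat(x)), ucenter(dmat(y))
    num = da = db = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j:
                num += A[i, j] * B[i, j]
                da += A[i, j] ** 2
                db += B[i, j] ** 2
    return num / np.sqrt(da * db)


def dcor_oracle_agreement(n_instances: int = 50, seed: int = 0) -> dict:
    """Max |r* - brute-force double-loop r*| over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 13))
        x = rng.normal(size=(n, int(rng.integers(1, 5))))
        y = rng.normal(size=(n, int(rng.integers(1, 5))))
        worst = max(worst, abs(dcor_ttest(x, y).r_star
                               - _brute_force_rstar(x, y)))
    return {"max_abs_difference": worst, "n": n_instances}


def u_centering_identity(n_instances: int = 20, seed: int = 0) -> dict:
    """Max |row sum| of U-centered matrices on random inputs."""
    from .dcor import u_centered_distances
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 40))
        A = u_centered_distances(rng.normal(size=(n, int(rng.integers(1, 8)))))
        worst = max(worst, float(np.abs(A.sum(axis=1)).max()))
    return {"max_abs_row_sum": worst, "n": n_instances}


def logcontrast_exactness(seed: int = 0) -> dict:
    """Zero-sum residual, closed-form agreement at lambda=0, scale invariance."""
    rng = np.random.default_rng(seed)
    comp, _ = simulate_microbiome(seed=seed)
    sub = top_k_taxa(comp, 50)
    Z = log_design(sub)
    beta = np.zeros(50)
    beta[rng.choice(50, 5, replace=False)] = EFFECT_PATTERN
    y = Z.to_numpy() @ beta + rng.normal(size=comp.n_samples)
    model = LogContrastModel(y, Z)
    Q, q, _, _ = model._stats()
    grid = model.lambda_grid(40)
    path = _zerosum.solve_path(Q, q, grid)
    max_zero_sum = float(np.abs(path.sum(axis=1)).max())
    ls = model.fit(0.0)
    tiny = _zerosum.solve_zerosum(Q, q, 1e-10)[0]
    ls_diff = float(np.abs(ls.beta.to_numpy()
                           - _zerosum.constrained_ls(Q, q)).max())
    ls_diff = max(ls_diff, float(np.abs(
        tiny - _zerosum.constrained_ls(Q, q)).max()))
    # per-sample count rescaling
    counts = sub.counts if sub.counts is not None else sub.proportions * 1e5
    scale = rng.uniform(0.2, 5.0, size=comp.n_samples)
    from .containers import FeatureTable, to_composition
    comp2 = to_composition(FeatureTable(counts * scale[:, None]))
    r1 = LogContrastModel(y, log_design(sub)).fit(float(grid[20]))
    r2 = LogContrastModel(y, log_design(comp2)).fit(float(grid[20]))
    rescale_diff = float(np.abs(r1.beta.to_numpy()
                                - r2.beta.to_numpy()).max())
    return {"max_zero_sum_violation": max_zero_sum,
            "lambda0_oracle_diff": ls_diff,
            "rescaling_diff": rescale_diff,
            "n": comp.n_samples}


def stability_recovery(n_reps: int = 20, n: int = 136, k: int = 50,
                       effect_scale: float = 0.8, n_bootstrap: int = 100,
                       threshold: int = 70, n_lambda: int = 40,
                       folds: int = 10, seed: int = 0) -> dict:
    """Support recovery of bootstrap stability selection on planted effects.

    Each repetition draws a fresh two-enterotype composition, plants the
    fixed zero-sum pattern (scaled by ``effect_scale``) on five of the
    top-k genera, and measures sensitivity (planted taxa selected) and the
    per-null-taxon false selection rate.
    """
    sens, fsr = [], []
    for rep in range(n_reps):
        comp, _ = simulate_microbiome(seed=seed + 1000 + rep, n=n)
        Z = log_design(top_k_taxa(comp, k))
        rng = np.random.default_rng(seed + 2000 + rep)
        chosen = rng.choice(k, size=5, replace=False)
        beta = np.zeros(k)
        beta[chosen] = EFFECT_PATTERN * effect_scale
        y = Z.to_numpy() @ beta + rng.normal(size=n)
        prof = stability_select(Z, y, n_bootstrap=n_bootstrap,
                                threshold=threshold, folds=folds,
                                n_lambda=n_lambda,
                                seed=seed + 3000 + rep)
        selected = set(prof.selected)
        true = {Z.columns[j] for j in chosen}
        sens.append(len(selected & true) / len(true))
        fsr.append(len(selected - true) / (k - len(true)))
    return {"sensitivity": float(np.mean(sens)),
            "false_selection_rate": float(np.mean(fsr)),
            "n": n_reps}


def mediation_recovery(n_reps: int = 50, n: int = 500,
                       n_bootstrap: int = 500, seed: int = 0) -> dict:
    """Recovery of a planted total indirect effect and null CI coverage."""
    ests = []
    truth_total = None
    for rep in range(n_reps):
        d, comp, y, truth = simulate_mediation_benchmark(n=n, seed=seed + rep)
        truth_total = truth["total_indirect"]
        med = CompositionalMediation(d, comp, y)
        res = med.fit(n_bootstrap=10, seed=seed + rep)  # point estimate only
        ests.append(res.total_indirect)
    covered = 0
    for rep in range(n_reps):
        d, comp, y, _ = simulate_mediation_benchmark(
            n=n, a_vals=None, seed=seed + 5000 + rep)
        res = CompositionalMediation(d, comp, y).fit(
            n_bootstrap=n_bootstrap, seed=seed + 6000 + rep)
        lo, hi = res.total_ci
        covered += lo <= 0.0 <= hi
    return {"mean_estimate": float(np.mean(ests)),
            "true_total_indirect": float(truth_total),
            "relative_error": float(abs(np.mean(ests) - truth_total)
                                    / abs(truth_total)),
            "null_ci_coverage": covered / n_reps,
            "n": n_reps}


def pam_optimality(n_instances: int = 100, n: int = 8, k: int = 2,
                   seed: int = 0) -> dict:
    """Fraction of random instances where PAM cost equals the enumerated optimum."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_instances):
        X = rng.normal(size=(n, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        model = pam_cluster(D, k)
        best = min(D[:, list(m)].min(axis=1).sum()
                   for m in itertools.combinations(range(n), k))
        hits += abs(model.total_cost - best) <= 1e-10
    return {"fraction_optimal": hits / n_instances, "n": n_instances}


def enterotype_recovery(seed: int = 0) -> dict:
    """k selection, label agreement and marker-family ranking on the preset."""
    comp, truth = simulate_microbiome(seed=seed)
    model = choose_enterotypes(comp)
    ari = adjusted_rand_score(truth.enterotype_labels.values,
                              model.labels.values)
    fam_map = {}
    others = 0
    for t in comp.taxon_ids:
        if t in truth.marker_taxa:
            fam_map[t] = "Ruminococcaceae"
        else:
            fam_map[t] = f"family_{others // 8 + 1:02d}"
            others += 1
    labels = model.labels if model.k == 2 else truth.enterotype_labels
    _, fam_tab, _ = enterotype_characterize(comp, labels,
                                            taxa_level_map=fam_map)
    rank = int(fam_tab.index[fam_tab["variable"] == "Ruminococcaceae"][0]) + 1
    return {"chosen_k": model.k, "label_ari": float(ari),
            "marker_family_rank": rank, "n": comp.n_samples}


def module_recovery(seed: int = 0) -> dict:
    """Planted-module recovery and eigenvalue-factor agreement on the preset."""
    study = simulate_study(seed=seed)
    truth = study["truth"]
    metab = study["metabolites"]
    metab_n = int_table(metab)
    power = soft_threshold_power(metab_n)
    assign = detect_modules(metab_n, power)
    true_labels = [truth.module_assignment[v] for v in metab_n.variable_ids]
    pred = [assign.labels[v] for v in metab_n.variable_ids]
    ari = adjusted_rand_score(true_labels, pred)
    ev, _ = module_eigenvalues(metab_n, assign)
    factors = truth.module_factors
    best_corr = [float(factors.corrwith(ev.scores[m]).abs().max())
                 for m in assign.module_names]
    return {"label_ari": float(ari),
            "n_modules_found": len(assign.module_names),
            "min_eigen_factor_corr": (min(best_corr) if best_corr else 0.0),
            "n": metab_n.n_variables}


def interaction_calibration_power(n: int = 136, n_null: int = 2500,
                                  delta: float = 0.5, n_power_reps: int = 50,
                                  noise_sd: float = 0.75,
                                  seed: int = 0) -> dict:
    """Type-I error of the interaction scan and power for a planted delta."""
    rng = np.random.default_rng(seed)
    e = np.array([0.0] * 54 + [1.0] * (n - 54))
    rej = 0
    for _ in range(n_null):
        d = rng.normal(size=n)
        m = rng.normal(size=n)
        _, _, p, _ = _ols_interaction(d, m, e)
        rej += p < 0.05
    hits = 0
    for rep in range(n_power_reps):
        r = np.random.default_rng(seed + 7000 + rep)
        d = r.normal(size=n)
        m = delta * d * e + r.normal(size=n) * noise_sd
        _, _, p, _ = _ols_interaction(d, m, e)
        hits += p < 0.01
    return {"null_type1": rej / n_null, "power": hits / n_power_reps,
            "n": n}


def preprocess_chain(seed: int = 0) -> dict:
    """Dedup of planted Spearman blocks, Shapiro pass rate, orthogonality."""
    diet, meta, truth = simulate_diet(n=136, k=91, seed=seed)
    out, report = preprocess_diet(diet, meta)
    blocks_ok = all(
        sum(v in out.variable_ids for v in members) == 1
        for members in truth.diet_blocks.values()
    )
    # INT'd continuous variables pass the Shapiro screen
    tabled = int_table(diet)
    kept, _ = shapiro_screen(tabled)
    shapiro_pass = kept.n_variables / diet.n_variables
    kcal = pd.to_numeric(meta.data["total_kcal"]).to_numpy()
    gender = pd.factorize(meta.data["gender"])[0].astype(float)
    vals = out.values
    viol = 0.0
    for cov in (kcal, gender):
        c = cov - cov.mean()
        c = c / np.linalg.norm(c)
        viol = max(viol, float(np.abs(vals.T @ c).max() / np.sqrt(len(c))))
    return {"one_representative_per_block": bool(blocks_ok),
            "shapiro_pass_fraction": float(shapiro_pass),
            "max_orthogonality_violation": viol,
            "n": diet.n_samples}
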