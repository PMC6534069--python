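"""Synthetic diet-microbiome-metabolome cohorts with planted ground truth.

Because the study's subject-level tables are not deposited, every
downstream stage is exercised on simulated data whose generating effects
are recorded exactly:

* microbiome: a logistic-normal-multinomial mixture with two enterotypes --
  per-sample log abundances are multivariate normal around the sample's
  enterotype center, closed through softmax, and counted with a multinomial
  at log-normal library size. One taxon block ("Ruminococcaceae-like") has
  an elevated center in enterotype 2, mirroring the family that separates
  real gut enterotypes.
* diet: Gaussian-copula blocks with prescribed within-block Spearman
  correlation (so the dedup stage has planted clusters to collapse), plus a
  metadata table with gender and total caloric intake.
* metabolome: module factors + sparse zero-sum taxon effects on log
  composition + diet main effects + diet x enterotype interactions +
  Gaussian noise; mediation triplets arise by giving a diet variable both an
  a-path into the (clr) composition and a b-path into a metabolite.

Default scale is the cohort's: n=136 samples, 130 genera, 91 dietary
variables and 200 metabolites (a desk-scale metabolome; a ``full_scale``
preset widens it to 812).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CompositionMatrix, FeatureTable, SampleMetadata

__all__ = ["GroundTruth", "simulate_microbiome", "simulate_diet",
           "simulate_metabolome", "simulate_study"]

ENTEROTYPE_MIX = (54 / 136, 82 / 136)  # observed enterotype split at n=136


@dataclass
class GroundTruth:
    """Everything planted by the generator, recorded exactly."""

    enterotype_labels: pd.Series | None = None
    enterotype_centers: np.ndarray | None = None  # 2 x g, log scale
    marker_taxa: list[str] = field(default_factory=list)
    marker_shift: float = 0.0
    diet_blocks: dict[int, list[str]] = field(default_factory=dict)
    diet_block_rho: dict[int, float] = field(default_factory=dict)
    diet_taxon_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    taxon_metabolite_coefs: dict[str, dict[str, float]] = field(default_factory=dict)
    diet_metabolite_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    interaction_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    module_assignment: dict[str, str] = field(default_factory=dict)
    module_loading: float = 0.0
    module_factors: pd.DataFrame | None = None
    mediation_triplets: list[dict] = field(default_factory=list)
    noise_sd: float = 1.0

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        for name in self.__dataclass_fields__:
            val = getattr(other, name)
            if val is None:
                continue
            if isinstance(val, (dict, list)) and not val:
                continue
            if isinstance(val, float) and val == 0.0:
                continue
            setattr(self, name, val)
        return self


def _spearman_to_pearson(rho_s: float) -> float:
    """Copula calibration: Pearson rho giving the target Spearman for Gaussians."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def simulate_microbiome(
    n: int = 136,
    g: int = 130,
    enterotype_mix=ENTEROTYPE_MIX,
    depth_log_mean: float = np.log(1e5),
    depth_log_sd: float = 0.3,
    marker_block: int = 8,
    marker_start: int | None = None,
    marker_shift: float = 3.0,
    log_sd: float = 0.8,
    deterministic_labels: bool = True,
    return_latent: bool = False,
    seed: int = 0,
):
    """Two-enterotype logistic-normal-multinomial composition.

    Taxon base log-abundances decay linearly so mean relative abundances are
    graded (a meaningful top-50). The ``marker_block`` taxa starting at
    abundance rank ``marker_start`` form the "Ruminococcaceae-like" family
    whose center is raised by ``marker_shift`` (log units) in enterotype 2;
    the mid-rank placement lets the family swing from minor to dominant
    between enterotypes while closure barely moves the other families.
    With ``deterministic_labels`` the label counts are exactly
    round(n * mix); otherwise labels are iid draws.

    Returns (CompositionMatrix, GroundTruth); with ``return_latent`` the
    noiseless softmax proportions are attached for closed-form checks.
    """
    if n < 10 or g < 10:
        raise ValueError("need n >= 10 and g >= 10")
    mix = np.asarray(enterotype_mix, dtype=float)
    if (mix <= 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("mixture proportions must be positive and sum to 1")
    if log_sd <= 0 or depth_log_sd < 0:
        raise ValueError("degenerate covariance")
    rng = np.random.default_rng(seed)
    base = np.linspace(4.0, -4.0, g)  # graded abundance spectrum with rare tail
    centers = np.vstack([base, base])
    if marker_start is None:
        marker_start = min(16, g - marker_block)  # mid-rank at full scale
    if marker_start < 0 or marker_start + marker_block > g:
        raise ValueError("marker block exceeds taxon count")
    m_lo, m_hi = marker_start, marker_start + marker_block
    centers[1, m_lo:m_hi] += marker_shift
    if deterministic_labels:
        n1 = int(round(n * mix[0]))
        labels = np.array([1] * n1 + [2] * (n - n1))
    else:
        labels = rng.choice([1, 2], size=n, p=mix)
    latent = centers[labels - 1] + rng.normal(scale=log_sd, size=(n, g))
    expl = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs = expl / expl.sum(axis=1, keepdims=True)
    depth = np.exp(rng.normal(depth_log_mean, depth_log_sd, size=n))
    counts = np.vstack([
        rng.multinomial(int(max(10, d)), p) for d, p in zip(depth, probs)
    ])
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    taxon_ids = [f"genus_{j+1:03d}" for j in range(g)]
    for r, j in enumerate(range(m_lo, m_hi)):
        taxon_ids[j] = f"Ruminococcaceae_g{r+1}"
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    rowsums = counts_df.sum(axis=1).to_numpy()
    props = counts_df.div(counts_df.sum(axis=1), axis=0)
    if (rowsums == 0).any():  # pragma: no cover - astronomically unlikely
        raise RuntimeError("empty multinomial sample")
    comp = CompositionMatrix(props, counts=counts_df)
    truth = GroundTruth(
        enterotype_labels=pd.Series(labels, index=sample_ids, name="enterotype"),
        enterotype_centers=centers,
        marker_taxa=taxon_ids[m_lo:m_hi],
        marker_shift=marker_shift,
    )
    if return_latent:
        truth.latent_proportions = pd.DataFrame(  # type: ignore[attr-defined]
            probs, index=sample_ids, columns=taxon_ids)
    return comp, truth


def simulate_diet(
    n: int = 136,
    k: int = 91,
    block_spec=((3, 0.95), (3, 0.95), (4, 0.93)),
    seed: int = 0,
):
    """Gaussian-copula dietary variables with planted correlated blocks.

    ``block_spec`` is a list of (size, target within-block Spearman); the
    remaining variables are independent. Also returns a metadata table with
    gender (balanced binary) and total_kcal (log-normal around 2000).

    Returns (FeatureTable, SampleMetadata, GroundTruth).
    """
    sizes = [s for s, _ in block_spec]
    if sum(sizes) > k:
        raise ValueError("block sizes exceed number of variables")
    for _, r in block_spec:
        if not (0.0 <= r < 1.0):
            raise ValueError("block correlations must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cols = []
    truth = GroundTruth()
    var_ids = [f"diet_{j+1:03d}" for j in range(k)]
    pos = 0
    for b, (size, rho_s) in enumerate(block_spec):
        rho_p = _spearman_to_pearson(rho_s)
        cov = np.full((size, size), rho_p)
        np.fill_diagonal(cov, 1.0)
        block = rng.multivariate_normal(np.zeros(size), cov, size=n)
        cols.append(block)
        ids = var_ids[pos:pos + size]
        truth.diet_blocks[b] = ids
        truth.diet_block_rho[b] = rho_s
        pos += size
    n_free = k - pos
    if n_free:
        cols.append(rng.normal(size=(n, n_free)))
    X = np.hstack(cols)
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    diet = FeatureTable(pd.DataFrame(X, index=sample_ids, columns=var_ids))
    meta = SampleMetadata(pd.DataFrame({
        "gender": rng.choice(["F", "M"], size=n),
        "total_kcal": np.exp(rng.normal(np.log(2000.0), 0.2, size=n)),
        "batch": rng.choice(["batch1", "batch2"], size=n, p=[0.8, 0.2]),
        "bmi": np.clip(rng.normal(25.5, 4.0, size=n), 16, 45),
    }, index=sample_ids), required=("gender", "total_kcal"))
    return diet, meta, truth


def _zero_sum_effect(rng, taxa, n_active: int, scale: float) -> dict[str, float]:
    """Sparse coefficient vector over named taxa summing exactly to zero."""
    chosen = list(rng.choice(len(taxa), size=n_active, replace=False))
    vals = rng.normal(scale=scale, size=n_active)
    vals -= vals.mean()
    while np.any(np.abs(vals) < 0.3 * scale):  # keep effects detectable
        vals = rng.normal(scale=scale, size=n_active)
        vals -= vals.mean()
    return {taxa[j]: float(v) for j, v in zip(chosen, vals)}


def simulate_metabolome(
    composition: CompositionMatrix,
    diet: FeatureTable,
    enterotype_labels: pd.Series | None = None,
    m: int = 200,
    n_modules: int = 4,
    module_size: int = 25,
    module_loading: float = 0.9,
    n_taxon_affected: int = 10,
    taxa_per_metabolite: int = 5,
    taxon_effect_scale: float = 0.8,
    n_diet_affected: int = 5,
    diet_effect: float = 0.5,
    n_interactions: int = 2,
    interaction_effect: float = 0.5,
    n_mediation: int = 3,
    a_path: float = 0.8,
    b_path: float = 0.5,
    noise_sd: float = 0.75,
    zero_replacement: float | None = 0.5,
    effect_taxa_pool: int | None = 50,
    seed: int = 0,
):
    """Metabolites driven by modules, taxa, diet, and diet x enterotype terms.

    Layout of the m metabolites (disjoint roles, in order):
    ``n_modules`` blocks of ``module_size`` loading on independent factors;
    then ``n_taxon_affected`` metabolites each receiving a sparse zero-sum
    coefficient vector on log composition; then ``n_diet_affected`` with a
    diet main effect; then ``n_interactions`` with a diet x enterotype
    interaction; then ``n_mediation`` mediation outcomes wired to diet
    variables that also perturb the composition (handled by re-drawing the
    targeted taxa); the remainder is pure noise.

    Mediation triplets are created by adding ``a_path`` * diet to the latent
    log abundance of chosen taxa (shifting the composition itself) and a
    zero-sum b-path on the log composition of the outcome metabolite; the
    recorded total indirect effect is the exact sum over taxa of
    (clr a-path)_j * b_j.

    Returns (FeatureTable, CompositionMatrix, GroundTruth): the composition
    is returned because mediation wiring perturbs it.
    """
    rng = np.random.default_rng(seed)
    n = composition.n_samples
    if list(diet.sample_ids) != list(composition.sample_ids):
        raise ValueError("diet and composition are not sample-aligned")
    need = n_modules * module_size + n_taxon_affected + n_diet_affected \
        + n_interactions + n_mediation
    if need > m:
        raise ValueError(f"m={m} too small for requested structure ({need})")
    truth = GroundTruth(noise_sd=noise_sd)
    truth.module_loading = module_loading

    taxa = composition.taxon_ids
    diet_ids = diet.variable_ids
    # restrict planted taxon effects to the most abundant taxa so they stay
    # inside the analyzed top-k subcomposition
    if effect_taxa_pool is not None and effect_taxa_pool < len(taxa):
        means = composition.proportions.mean(axis=0)
        order = sorted(means.index, key=lambda t: (-means[t], t))
        pool = order[:effect_taxa_pool]
    else:
        pool = list(taxa)

    # --- mediation wiring first: it perturbs the composition -----------
    P = composition.values.copy()
    if (P == 0).any():
        if zero_replacement is None:
            raise ValueError("composition has zeros; set zero_replacement")
        nzmin = P[P > 0].min()
        delta = zero_replacement * nzmin
        zc = (P == 0).sum(axis=1)
        P = P * ((1.0 - zc * delta) / P.sum(axis=1))[:, None]
        P[composition.values == 0] = delta
    logP = np.log(P)
    med_diet_ids = list(rng.choice(diet_ids, size=n_mediation, replace=False)) \
        if n_mediation else []
    med_taxa_sets = []
    med_a_vals = []
    taxa_index = {t: j for j, t in enumerate(taxa)}
    for d_id in med_diet_ids:
        tset = [taxa_index[t] for t in rng.choice(pool, size=3, replace=False)]
        # heterogeneous per-taxon a-paths: a uniform a-path paired with a
        # zero-sum b on the same taxa would plant a total indirect of
        # exactly zero
        a_vals = a_path * rng.uniform(0.5, 1.5, size=len(tset)) \
            * rng.choice([-1.0, 1.0], size=len(tset))
        d = diet.data[d_id].to_numpy()
        d = (d - d.mean()) / d.std(ddof=0)
        for j, av in zip(tset, a_vals):
            logP[:, j] = logP[:, j] + av * d
        med_taxa_sets.append(tset)
        med_a_vals.append(a_vals)
        truth.diet_taxon_effects[d_id] = {
            taxa[j]: float(av) for j, av in zip(tset, a_vals)}
    # re-close after the log-scale perturbation
    P = np.exp(logP)
    P /= P.sum(axis=1, keepdims=True)
    comp_out = CompositionMatrix(
        pd.DataFrame(P, index=composition.proportions.index,
                     columns=composition.proportions.columns))
    logP = np.log(P)
    clr = logP - logP.mean(axis=1, keepdims=True)

    metab_ids = [f"met_{j+1:03d}" for j in range(m)]
    Y = rng.normal(scale=noise_sd, size=(n, m))
    col = 0

    # module structure
    factors = rng.normal(size=(n, n_modules))
    for mod in range(n_modules):
        for _ in range(module_size):
            Y[:, col] += module_loading * factors[:, mod]
            truth.module_assignment[metab_ids[col]] = f"M{mod+1}"
            col += 1
    truth.module_factors = pd.DataFrame(
        factors, index=composition.sample_ids,
        columns=[f"M{j+1}" for j in range(n_modules)])
    for j in range(col, m):
        truth.module_assignment[metab_ids[j]] = "unclustered"

    # sparse zero-sum taxon effects on log composition
    for _ in range(n_taxon_affected):
        eff = _zero_sum_effect(rng, pool, taxa_per_metabolite,
                               taxon_effect_scale)
        beta = np.array([eff.get(t, 0.0) for t in taxa])
        Y[:, col] += logP @ beta
        truth.taxon_metabolite_coefs[metab_ids[col]] = eff
        col += 1

    # diet main effects
    free_diet = [d for d in diet_ids if d not in med_diet_ids]
    for i in range(n_diet_affected):
        d_id = free_diet[i % len(free_diet)]
        d = diet.data[d_id].to_numpy()
        d = (d - d.mean()) / d.std(ddof=0)
        Y[:, col] += diet_effect * d
        truth.diet_metabolite_effects.setdefault(metab_ids[col], {})[d_id] = \
            diet_effect
        col += 1

    # diet x enterotype interactions
    if n_interactions and enterotype_labels is None:
        raise ValueError("interactions need enterotype labels")
    for i in range(n_interactions):
        d_id = free_diet[(n_diet_affected + i) % len(free_diet)]
        d = diet.data[d_id].to_numpy()
        d = (d - d.mean()) / d.std(ddof=0)
        e = (enterotype_labels.loc[composition.sample_ids] == 2).to_numpy()
        Y[:, col] += interaction_effect * d * e
        truth.interaction_effects[(d_id, metab_ids[col])] = interaction_effect
        col += 1

    # mediation outcomes
    g = len(taxa)
    for d_id, tset, a_vals in zip(med_diet_ids, med_taxa_sets, med_a_vals):
        b = _zero_sum_effect(rng, [taxa[j] for j in tset], len(tset), b_path)
        bvec = np.array([b.get(t, 0.0) for t in taxa])
        Y[:, col] += logP @ bvec
        # clr-scale a-path: raising taxon j by a_j*d shifts every clr
        # coordinate by -mean(a)*d and the targeted ones by a_j*d on top;
        # with b zero-sum over ALL taxa only the targeted terms survive
        # in sum, but per-taxon contributions use the full clr a-path
        a_clr = np.full(g, -a_vals.sum() / g)
        for j, av in zip(tset, a_vals):
            a_clr[j] += av
        total_indirect = float(a_clr @ bvec)
        truth.mediation_triplets.append({
            "diet": d_id, "metabolite": metab_ids[col],
            "taxa": [taxa[j] for j in tset],
            "a_paths": {taxa[j]: float(av) for j, av in zip(tset, a_vals)},
            "a_clr": a_clr, "b": b,
            "per_taxon_indirect": {t: float(a_clr[taxa.index(t)] * b[t])
                                   for t in b},
            "total_indirect": total_indirect,
            "direct_effect": 0.0,
        })
        col += 1

    metab = FeatureTable(pd.DataFrame(Y, index=composition.sample_ids,
                                      columns=metab_ids))
    return metab, comp_out, truth


def simulate_mediation_benchmark(
    n: int = 500,
    g: int = 50,
    a_vals=(0.8, 0.5, -0.4),
    b_vals=(0.5, 0.2, -0.7),
    target_total: float | None = 0.40,
    direct_effect: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """A single mediation triplet with an exactly known total indirect effect.

    Standard-normal diet d perturbs the latent log abundances of three
    abundant taxa by ``a_vals * d``; the outcome is ``b' log(composition) +
    direct_effect * d + noise`` with ``b`` zero-sum on the same taxa. The
    planted total indirect effect is sum_j a_j b_j; when ``target_total`` is
    given, ``b`` is rescaled so the sum equals it exactly. With
    ``a_vals=None`` the a-path is null (diet independent of composition).

    Returns (d, CompositionMatrix, y, truth_dict).
    """
    rng = np.random.default_rng(seed)
    b = np.asarray(b_vals, dtype=float)
    if abs(b.sum()) > 1e-12:
        raise ValueError("b_vals must sum to zero")
    null_a = a_vals is None
    a = np.zeros(3) if null_a else np.asarray(a_vals, dtype=float)
    if not null_a and target_total is not None:
        b = b * (target_total / float(a @ b))
    d = rng.normal(size=n)
    base = np.linspace(2.0, -2.0, g)
    latent = base + rng.normal(scale=0.8, size=(n, g))
    tset = [0, 2, 4]  # abundant taxa, so count noise barely attenuates paths
    for j, aj in zip(tset, a):
        latent[:, j] += aj * d
    expl = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs = expl / expl.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(100000, p) for p in probs])
    counts = np.maximum(counts, 1)  # abundant-taxon benchmark: no zeros
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    taxon_ids = [f"t{j+1:02d}" for j in range(g)]
    counts_df = pd.DataFrame(counts.astype(float), index=sample_ids,
                             columns=taxon_ids)
    comp = CompositionMatrix(counts_df.div(counts_df.sum(axis=1), axis=0),
                             counts=counts_df)
    logP = np.log(comp.values)
    bvec = np.zeros(g)
    for j, bj in zip(tset, b):
        bvec[j] = bj
    y = logP @ bvec + direct_effect * d + rng.normal(scale=noise_sd, size=n)
    truth = {
        "taxa": [taxon_ids[j] for j in tset],
        "a": dict(zip([taxon_ids[j] for j in tset], a)),
        "b": dict(zip([taxon_ids[j] for j in tset], b)),
        "total_indirect": float(a @ b),
        "direct_effect": direct_effect,
    }
    return d, comp, y, truth


def simulate_study(
    n: int = 136,
    g: int = 130,
    k_diet: int = 91,
    m: int = 200,
    seed: int = 0,
    full_scale: bool = False,
    **metab_kwargs,
):
    """One coherent synthetic cohort: microbiome + diet + metabolome + truth.

    Returns a dict with keys ``composition``, ``diet``, ``metadata``,
    ``metabolites`` and ``truth``. ``full_scale`` widens the metabolome to
    812 features with 8 planted modules.
    """
    if full_scale:
        m = 812
        metab_kwargs.setdefault("n_modules", 8)
        metab_kwargs.setdefault("module_size", 30)
    comp, t1 = simulate_microbiome(n=n, g=g, seed=seed)
    diet, meta, t2 = simulate_diet(n=n, k=k_diet, seed=seed + 1)
    metab, comp, t3 = simulate_metabolome(
        comp, diet, enterotype_labels=t1.enterotype_labels, m=m,
        seed=seed + 2, **metab_kwargs,
    )
    truth = GroundTruth().merge(t1).merge(t2).merge(t3)
    return {"composition": comp, "diet": diet, "metadata": meta,
            "metabolites": metab, "truth": truth}
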