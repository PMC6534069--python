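"""Enterotype clustering, characterization, and interaction analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from triomix.containers import CompositionMatrix, FeatureTable
from triomix.enterotype import (ecological_distance, enterotype_characterize,
                                interaction_scan, pam_cluster,
                                choose_enterotypes, stratified_association,
                                _ols_interaction)
from triomix.simulate import simulate_microbiome


def _comp(rows):
    arr = np.asarray(rows, dtype=float)
    df = pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])],
                      columns=[f"t{j}" for j in range(arr.shape[1])])
    return CompositionMatrix(df.div(df.sum(axis=1), axis=0))


class TestDistances:
    def test_identical_samples_distance_zero(self):
        c = _comp([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]])
        for name in ("euclidean", "bray-curtis", "jaccard"):
            assert ecological_distance(c, name)[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_attain_one(self):
        c = _comp([[0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]])
        assert ecological_distance(c, "bray-curtis")[0, 1] == pytest.approx(1.0)
        assert ecological_distance(c, "jaccard")[0, 1] == pytest.approx(1.0)

    def test_forced_arithmetic_case(self):
        c = _comp([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5]])
        assert ecological_distance(c, "bray-curtis")[0, 1] == pytest.approx(0.5)
        assert ecological_distance(c, "jaccard")[0, 1] == pytest.approx(2 / 3)

    def test_unknown_name_rejected(self, small_composition):
        with pytest.raises(ValueError, match="unknown distance"):
            ecological_distance(small_composition, "chebyshev")


def brute_force_pam_cost(D, k=2):
    n = D.shape[0]
    best = np.inf
    for meds in itertools.combinations(range(n), k):
        best = min(best, D[:, meds].min(axis=1).sum())
    return best


class TestPAM:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, size=(15, 2)),
                       rng.normal(5, 0.1, size=(15, 2))])
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        model = pam_cluster(D, 2)
        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, model.labels.values) == 1.0

    def test_matches_exhaustive_optimum_n8(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            X = rng.normal(size=(8, 3))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            model = pam_cluster(D, 2)
            assert model.total_cost == pytest.approx(
                brute_force_pam_cost(D, 2), abs=1e-10)

    def test_k_near_n_cost_bound(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(7, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        model = pam_cluster(D, 6)
        off = D[D > 0]
        assert model.total_cost <= off.min() + 1e-12 or \
            model.total_cost == pytest.approx(0.0)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pam_cluster(D, 2)


class TestChooseEnterotypes:
    def test_two_enterotype_preset_recovered(self):
        comp, truth = simulate_microbiome(seed=42)
        model = choose_enterotypes(comp)
        assert model.k == 2
        ari = adjusted_rand_score(truth.enterotype_labels.values,
                                  model.labels.values)
        assert ari >= 0.8
        assert model.pcoa_coords is not None
        # medoid group means separate on axis 1
        m1 = model.pcoa_coords.loc[model.labels == 1, "PCo1"].mean()
        m2 = model.pcoa_coords.loc[model.labels == 2, "PCo1"].mean()
        assert abs(m1 - m2) > 0

    def test_structureless_composition_flagged_weak(self):
        comp, _ = simulate_microbiome(seed=3, n=60, g=130, marker_shift=0.0)
        model = choose_enterotypes(comp, k_range=range(2, 4))
        assert model.weak_structure
        assert model.silhouette < 0.25

    def test_invariant_to_sample_order(self):
        comp, _ = simulate_microbiome(seed=5, n=40, g=30)
        model = choose_enterotypes(comp, k_range=range(2, 4))
        rng = np.random.default_rng(6)
        perm = [comp.sample_ids[i] for i in rng.permutation(40)]
        model_p = choose_enterotypes(comp.select_samples(perm),
                                     k_range=range(2, 4))
        assert model_p.silhouette == pytest.approx(model.silhouette, abs=1e-10)


class TestCharacterize:
    def test_marker_family_ranks_first(self):
        comp, truth = simulate_microbiome(seed=7)
        fam_map = {t: ("Ruminococcaceae" if t in truth.marker_taxa
                       else f"fam{hashable}" )
                   for hashable, t in enumerate(comp.taxon_ids)}
        taxon_tab, fam_tab, _ = enterotype_characterize(
            comp, truth.enterotype_labels, taxa_level_map=fam_map)
        assert fam_tab.iloc[0]["variable"] == "Ruminococcaceae"
        assert fam_tab.iloc[0]["mean_e2"] > fam_tab.iloc[0]["mean_e1"]

    def test_null_labels_give_uniform_pvalues(self):
        comp, _ = simulate_microbiome(seed=8, marker_shift=0.0)
        labels = pd.Series([1] * 54 + [2] * 82, index=comp.sample_ids)
        taxon_tab, _, _ = enterotype_characterize(comp, labels)
        ks = stats.kstest(taxon_tab["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_tiny_cluster_rejected(self, small_composition):
        labels = pd.Series([1, 1] + [2] * 8,
                           index=small_composition.sample_ids)
        with pytest.raises(ValueError, match="fewer than 3"):
            enterotype_characterize(small_composition, labels)


class TestInteraction:
    def test_swap_of_coding_negates_coefficient(self):
        rng = np.random.default_rng(9)
        n = 100
        d = rng.normal(size=n)
        e = (rng.random(n) < 0.5).astype(float)
        m = 0.4 * d * e + rng.normal(size=n)
        c1, t1, p1, _ = _ols_interaction(d, m, e)
        c2, t2, p2, _ = _ols_interaction(d, m, 1 - e)
        assert c1[3] == pytest.approx(-c2[3], abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_scan_reports_simple_slopes_and_dof(self):
        rng = np.random.default_rng(10)
        n = 60
        ids = [f"S{i}" for i in range(n)]
        labels = pd.Series([1] * 30 + [2] * 30, index=ids)
        diet = FeatureTable(pd.DataFrame(rng.normal(size=(n, 2)), index=ids,
                                         columns=["d0", "d1"]))
        met = FeatureTable(pd.DataFrame(rng.normal(size=(n, 3)), index=ids,
                                        columns=["m0", "m1", "m2"]))
        tab = interaction_scan(diet, met, labels)
        assert len(tab) == 6
        assert (tab.dof == n - 4).all()
        row = tab.iloc[0]
        assert row.slope_e2 == pytest.approx(
            row.slope_e1 + row.interaction_coef, abs=1e-12)

    def test_null_scan_calibrated(self):
        rng = np.random.default_rng(11)
        n = 136
        ids = [f"S{i}" for i in range(n)]
        labels = pd.Series([1] * 54 + [2] * 82, index=ids)
        diet = FeatureTable(pd.DataFrame(rng.normal(size=(n, 25)), index=ids,
                                         columns=[f"d{j}" for j in range(25)]))
        met = FeatureTable(pd.DataFrame(rng.normal(size=(n, 25)), index=ids,
                                        columns=[f"m{j}" for j in range(25)]))
        tab = interaction_scan(diet, met, labels)
        rate = (tab.interaction_p < 0.05).mean()
        assert 0.03 <= rate <= 0.07


class TestStratified:
    def test_constructed_association_in_one_stratum(self):
        rng = np.random.default_rng(12)
        n = 60
        labels = np.array([1] * 30 + [2] * 30)
        x = rng.normal(size=n)
        y = np.where(labels == 2, x, rng.normal(size=n))
        tab = stratified_association(x, y, labels)
        p1 = tab[tab.stratum == 1].iloc[0].p
        p2 = tab[tab.stratum == 2].iloc[0].p
        assert p2 < 1e-6 and p1 > 0.001

    def test_small_stratum_flagged(self):
        x = np.arange(9.0)
        y = x.copy()
        labels = np.array([1] * 4 + [2] * 5)
        tab = stratified_association(x, y, labels)
        assert tab[tab.stratum == 1].iloc[0].flag == "too few samples"
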