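"""Synthetic-cohort generator: recorded truth, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomix.simulate import (simulate_diet, simulate_mediation_benchmark,
                              simulate_metabolome, simulate_microbiome,
                              simulate_study)


class TestMicrobiome:
    def test_study_split_is_exact_with_deterministic_labels(self):
        comp, truth = simulate_microbiome(n=136, g=130, seed=0)
        counts = truth.enterotype_labels.value_counts()
        assert counts[1] == 54 and counts[2] == 82

    def test_identical_centers_null_marker_difference(self):
        tvals = []
        for seed in range(6):
            comp, truth = simulate_microbiome(seed=seed, marker_shift=0.0,
                                              n=80, g=40)
            marker = comp.proportions[truth.marker_taxa].sum(axis=1)
            g1 = marker[truth.enterotype_labels == 1]
            g2 = marker[truth.enterotype_labels == 2]
            tvals.append(stats.ttest_ind(g1, g2, equal_var=False).statistic)
        assert np.abs(np.mean(tvals)) < 1.0

    def test_latent_proportions_are_softmax_of_centers(self):
        comp, truth = simulate_microbiome(seed=1, n=20, g=15,
                                          return_latent=True)
        latent = truth.latent_proportions
        np.testing.assert_allclose(latent.sum(axis=1), 1.0, atol=1e-12)

    def test_fixed_seed_bitwise_reproducible(self):
        a, _ = simulate_microbiome(seed=5)
        b, _ = simulate_microbiome(seed=5)
        pd.testing.assert_frame_equal(a.proportions, b.proportions)

    def test_degenerate_covariance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            simulate_microbiome(log_sd=0.0)


class TestDiet:
    def test_copula_calibration_hits_spearman_target(self):
        diet, _, truth = simulate_diet(n=500, k=10,
                                       block_spec=((3, 0.95),), seed=0)
        members = truth.diet_blocks[0]
        rho = stats.spearmanr(diet.data[members]).statistic
        pairs = rho[np.triu_indices(3, 1)]
        assert np.all(pairs >= 0.90) and np.all(pairs <= 0.99)

    def test_singleton_blocks_independent(self):
        diet, _, _ = simulate_diet(n=400, k=20, block_spec=(), seed=1)
        rho = stats.spearmanr(diet.values).statistic
        off = np.abs(rho[np.triu_indices(20, 1)])
        assert np.median(off) < 0.06

    def test_variable_count_matches_request(self):
        diet, meta, _ = simulate_diet(n=50, k=91, seed=2)
        assert diet.n_variables == 91
        assert {"gender", "total_kcal"} <= set(meta.data.columns)

    def test_oversized_blocks_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate_diet(k=5, block_spec=((10, 0.9),))


class TestMetabolome:
    def test_null_effects_leave_taxa_uncorrelated(self):
        comp, truth = simulate_microbiome(seed=3, n=100, g=30)
        diet, _, _ = simulate_diet(n=100, k=10, seed=3)
        metab, _, _ = simulate_metabolome(
            comp, diet, enterotype_labels=truth.enterotype_labels,
            m=40, n_modules=0, module_size=0, n_taxon_affected=0,
            n_diet_affected=0, n_interactions=0, n_mediation=0,
            noise_sd=1.0, seed=4)
        cors = [np.corrcoef(metab.values[:, j], comp.values[:, 0])[0, 1]
                for j in range(40)]
        assert abs(np.mean(cors)) < 0.05

    def test_noise_moments_match_spec(self):
        comp, truth = simulate_microbiome(seed=5, n=136, g=20)
        diet, _, _ = simulate_diet(n=136, k=12, seed=5)
        metab, _, _ = simulate_metabolome(
            comp, diet, enterotype_labels=truth.enterotype_labels,
            m=30, n_modules=0, module_size=0, n_taxon_affected=0,
            n_diet_affected=0, n_interactions=0, n_mediation=0,
            noise_sd=1.0, seed=6)
        tol = 3 / np.sqrt(136)
        assert abs(metab.values.mean()) < tol
        assert abs(metab.values.std() - 1.0) < tol

    def test_module_members_correlate_as_planted(self):
        study = simulate_study(seed=6)
        truth = study["truth"]
        metab = study["metabolites"]
        members = [v for v, m in truth.module_assignment.items() if m == "M1"]
        C = np.corrcoef(metab.data[members].to_numpy(), rowvar=False)
        mean_pair = C[np.triu_indices(len(members), 1)].mean()
        # loading 0.9, noise 0.75: expected pair correlation
        # 0.81/(0.81+0.5625) ~= 0.59
        assert mean_pair >= 0.45

    def test_planted_truth_fields_complete(self):
        study = simulate_study(seed=7)
        truth = study["truth"]
        assert truth.enterotype_labels is not None
        assert truth.marker_taxa
        assert truth.diet_blocks
        assert truth.taxon_metabolite_coefs
        assert truth.interaction_effects
        assert len(truth.mediation_triplets) == 3
        for t in truth.mediation_triplets:
            per_taxon = sum(t["per_taxon_indirect"].values())
            a_clr = np.asarray(t["a_clr"])
            b = t["b"]
            assert abs(sum(b.values())) < 1e-12

    def test_zero_sum_of_planted_taxon_coefs(self):
        study = simulate_study(seed=8)
        for eff in study["truth"].taxon_metabolite_coefs.values():
            assert abs(sum(eff.values())) < 1e-12


class TestMediationBenchmark:
    def test_recorded_total_is_exact_product_sum(self):
        d, comp, y, truth = simulate_mediation_benchmark(n=50, seed=0)
        a = np.array([truth["a"][t] for t in truth["taxa"]])
        b = np.array([truth["b"][t] for t in truth["taxa"]])
        assert truth["total_indirect"] == pytest.approx(float(a @ b),
                                                        abs=1e-12)
        assert truth["total_indirect"] == pytest.approx(0.40, abs=1e-12)

    def test_nonzero_b_requires_zero_sum(self):
        with pytest.raises(ValueError, match="sum to zero"):
            simulate_mediation_benchmark(b_vals=(0.5, 0.5, 0.5))


def test_study_tables_sample_aligned_and_deterministic():
    s1 = simulate_study(seed=9)
    s2 = simulate_study(seed=9)
    assert s1["composition"].sample_ids == s1["diet"].sample_ids \
        == s1["metabolites"].sample_ids == s1["metadata"].sample_ids
    pd.testing.assert_frame_equal(s1["metabolites"].data,
                                  s2["metabolites"].data)
    pd.testing.assert_frame_equal(s1["composition"].proportions,
                                  s2["composition"].proportions)
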