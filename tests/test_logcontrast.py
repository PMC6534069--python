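"""Zero-sum log-contrast lasso: exactness, invariances, CV, stability selection."""

import numpy as np
import pandas as pd
import pytest

from triomix import _zerosum
from triomix.containers import CompositionMatrix, FeatureTable, to_composition
from triomix.logcontrast import (LogContrastModel, association_matrix,
                                 log_design, stability_select, top_k_taxa)
from triomix.simulate import simulate_microbiome


def _comp_from_counts(counts):
    counts = np.asarray(counts, dtype=float)
    df = pd.DataFrame(counts, index=[f"S{i}" for i in range(counts.shape[0])],
                      columns=[f"t{j}" for j in range(counts.shape[1])])
    return to_composition(FeatureTable(df))


class TestTopK:
    def test_identity_when_k_equals_all(self, small_composition):
        out = top_k_taxa(small_composition, small_composition.n_taxa)
        np.testing.assert_allclose(out.values, small_composition.values)

    def test_zero_abundance_taxon_never_kept(self):
        comp = _comp_from_counts([[5, 3, 0], [2, 8, 0]])
        out = top_k_taxa(comp, 2)
        assert "t2" not in out.taxon_ids

    def test_default_study_scale(self):
        comp, _ = simulate_microbiome(seed=0)
        out = top_k_taxa(comp, 50)
        assert out.n_taxa == 50
        np.testing.assert_allclose(out.values.sum(axis=1), 1, atol=1e-9)


class TestLogDesign:
    def test_forced_arithmetic_of_half_min_replacement(self):
        comp = CompositionMatrix(pd.DataFrame(
            [[0.5, 0.5, 0.0]], index=["S0"], columns=list("abc")))
        Z = log_design(comp)
        np.testing.assert_allclose(np.exp(Z.to_numpy()),
                                   [[0.375, 0.375, 0.25]], atol=1e-12)

    def test_zero_free_rows_log_exactly(self):
        comp = _comp_from_counts([[1, 1, 2], [3, 1, 4]])
        np.testing.assert_allclose(log_design(comp).to_numpy(),
                                   np.log(comp.values), atol=1e-15)

    def test_count_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(8, 5)).astype(float)
        scale = rng.uniform(0.5, 20.0, size=8)
        Z1 = log_design(_comp_from_counts(counts))
        Z2 = log_design(_comp_from_counts(counts * scale[:, None]))
        np.testing.assert_allclose(Z1.to_numpy(), Z2.to_numpy(), atol=1e-12)


class TestFit:
    @pytest.fixture
    def problem(self):
        rng = np.random.default_rng(1)
        n, k = 60, 8
        Z = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"t{j}" for j in range(k)])
        beta = np.array([1.0, -1.0, 0.5, -0.5, 0, 0, 0, 0])
        y = 2.0 + Z.to_numpy() @ beta + rng.normal(size=n) * 0.3
        return Z, y, beta

    def test_zero_sum_holds_along_entire_path(self, problem):
        Z, y, _ = problem
        m = LogContrastModel(y, Z)
        grid = m.lambda_grid(30)
        Q, q, _, _ = m._stats()
        path = _zerosum.solve_path(Q, q, grid)
        assert np.abs(path.sum(axis=1)).max() <= 1e-8

    def test_lambda_zero_matches_constrained_least_squares(self, problem):
        Z, y, _ = problem
        m = LogContrastModel(y, Z)
        res = m.fit(0.0)
        Q, q, zbar, ybar = m._stats()
        oracle = _zerosum.constrained_ls(Q, q)
        np.testing.assert_allclose(res.beta.to_numpy(), oracle, atol=1e-8)
        assert abs(res.beta.sum()) <= 1e-8

    def test_lambda_max_gives_null_model(self, problem):
        Z, y, _ = problem
        m = LogContrastModel(y, Z)
        lam_max = m.lambda_grid(2)[0]
        res = m.fit(lam_max * 1.0001)
        assert np.all(res.beta.to_numpy() == 0)

    def test_kkt_certified(self, problem):
        Z, y, _ = problem
        res = LogContrastModel(y, Z).fit(0.05)
        assert res.kkt <= 1e-6

    def test_compositional_scale_invariance_end_to_end(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 200, size=(50, 6)).astype(float)
        y = rng.normal(size=50)
        scale = rng.uniform(0.1, 10, size=50)
        r1 = LogContrastModel(y, log_design(_comp_from_counts(counts))).fit(0.02)
        r2 = LogContrastModel(
            y, log_design(_comp_from_counts(counts * scale[:, None]))).fit(0.02)
        np.testing.assert_allclose(r1.beta.to_numpy(), r2.beta.to_numpy(),
                                   atol=1e-8)


class TestCV:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        Z = pd.DataFrame(rng.normal(size=(50, 6)))
        y = rng.normal(size=50)
        a = LogContrastModel(y, Z).fit_cv(folds=5, n_lambda=20, seed=9)
        b = LogContrastModel(y, Z).fit_cv(folds=5, n_lambda=20, seed=9)
        assert a.lambda_selected == b.lambda_selected
        np.testing.assert_array_equal(a.beta.to_numpy(), b.beta.to_numpy())

    def test_pure_noise_selects_sparse_model(self):
        sizes = []
        for seed in range(5):
            rng = np.random.default_rng(40 + seed)
            Z = pd.DataFrame(rng.normal(size=(80, 10)))
            y = rng.normal(size=80)
            res = LogContrastModel(y, Z).fit_cv(folds=10, n_lambda=30,
                                                seed=seed)
            sizes.append(len(res.support))
        assert np.mean(sizes) <= 3.0

    def test_strong_signal_recovers_support(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            n, k = 200, 12
            Z = pd.DataFrame(rng.normal(size=(n, k)),
                             columns=[f"t{j}" for j in range(k)])
            beta = np.zeros(k)
            beta[:5] = [1.0, -1.0, 0.8, -0.5, -0.3]
            y = Z.to_numpy() @ beta + rng.normal(size=n) * 0.5
            res = LogContrastModel(y, Z).fit_cv(folds=10, n_lambda=30,
                                                seed=seed)
            hits += len(set(res.support) & {f"t{j}" for j in range(5)}) >= 4
        assert hits >= 4

    def test_cv_curve_shapes(self):
        rng = np.random.default_rng(4)
        Z = pd.DataFrame(rng.normal(size=(60, 5)))
        y = rng.normal(size=60)
        res = LogContrastModel(y, Z).fit_cv(folds=6, n_lambda=25, seed=0)
        assert len(res.cv_mean_error) == len(res.lambda_grid) == 25
        assert len(res.cv_se) == 25


class TestStabilitySelection:
    def test_threshold_is_strict(self):
        rng = np.random.default_rng(5)
        Z = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"t{j}" for j in range(5)])
        y = 2 * Z["t0"].to_numpy() - 2 * Z["t1"].to_numpy() \
            + rng.normal(size=60) * 0.1
        prof = stability_select(Z, y, n_bootstrap=10, threshold=10,
                                folds=5, n_lambda=15, seed=0)
        assert prof.selected == []  # count can never exceed n_bootstrap

    def test_planted_effects_selected_nulls_mostly_not(self):
        comp, _ = simulate_microbiome(seed=20)
        Z = log_design(top_k_taxa(comp, 50))
        rng = np.random.default_rng(21)
        beta = np.zeros(50)
        beta[[3, 11, 19, 27, 35]] = np.array([1, -1, 0.8, -0.5, -0.3]) * 0.8
        y = Z.to_numpy() @ beta + rng.normal(size=136)
        prof = stability_select(Z, y, n_bootstrap=30, threshold=21,
                                folds=10, n_lambda=30, seed=22)
        true = {Z.columns[j] for j in (3, 11, 19, 27, 35)}
        assert len(set(prof.selected) & true) >= 4
        null_rate = len(set(prof.selected) - true) / 45
        assert null_rate <= 0.25

    def test_null_false_selection_probability_low(self):
        """Per-taxon false selection stays near zero on pure-noise responses
        under the full selection rule (100 bootstraps, strict >70)."""
        rates = []
        for seed in range(2):
            comp, _ = simulate_microbiome(seed=60 + seed)
            Z = log_design(top_k_taxa(comp, 50))
            y = np.random.default_rng(70 + seed).normal(size=136)
            prof = stability_select(Z, y, n_bootstrap=100, threshold=70,
                                    folds=10, n_lambda=20, seed=seed)
            rates.append(len(prof.selected) / 50)
        assert np.mean(rates) <= 0.05


class TestAssociationMatrix:
    def test_duplicated_response_gets_identical_profile(self):
        comp, _ = simulate_microbiome(seed=30, n=50, g=20)
        rng = np.random.default_rng(31)
        y = rng.normal(size=50)
        resp = FeatureTable(pd.DataFrame(
            {"same_a": y, "same_b": y * 1.0}, index=comp.sample_ids))
        # same per-response seed derivation applies only to identical ids;
        # here check that scanning twice is reproducible
        t1 = association_matrix(resp, comp, k=10, n_bootstrap=8, threshold=6,
                                folds=5, n_lambda=10, seed=1)
        t2 = association_matrix(resp, comp, k=10, n_bootstrap=8, threshold=6,
                                folds=5, n_lambda=10, seed=1)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_response_set_empty_table(self, small_composition):
        resp = FeatureTable(pd.DataFrame(
            index=small_composition.sample_ids, columns=[], dtype=float))
        tab = association_matrix(resp, small_composition, k=3, n_bootstrap=2,
                                 threshold=1, folds=2, n_lambda=5, seed=0)
        assert len(tab) == 0
        assert list(tab.columns) == ["response", "taxon", "selection_count",
                                     "mean_coefficient", "selected"]
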