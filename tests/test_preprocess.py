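"""Normalization chain: imputation, INT, Shapiro screen, residual method, dedup."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomix.containers import FeatureTable, SampleMetadata
from triomix.preprocess import (dedup_correlated, impute_below_lod, int_table,
                                inverse_normal_transform, median_rescale,
                                preprocess_diet, residual_adjust,
                                shapiro_screen)


def _table(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return FeatureTable(pd.DataFrame(
        arr, index=[f"S{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])]))


class TestImputeAndRescale:
    def test_missing_replaced_by_column_minimum(self):
        t = _table([[1.2], [np.nan], [0.5]])
        out, rep = impute_below_lod(t)
        np.testing.assert_allclose(out.data["v0"], [1.2, 0.5, 0.5])
        assert rep.imputed_count["v0"] == 1

    def test_fully_observed_unchanged_and_all_missing_dropped(self):
        t = _table([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]])
        with pytest.warns(UserWarning, match="v1"):
            out, rep = impute_below_lod(t)
        assert out.variable_ids == ["v0"]
        np.testing.assert_array_equal(out.data["v0"], [1, 2, 3])
        assert not rep.kept("v1")

    def test_median_rescale_sets_median_to_one(self):
        t = _table([[2.0], [4.0], [6.0]])
        out = median_rescale(t)
        np.testing.assert_allclose(out.data["v0"], [0.5, 1.0, 1.5])
        t2 = _table([[1.0], [1.0], [1.0]])
        np.testing.assert_allclose(median_rescale(t2).values, t2.values)

    def test_zero_median_errors(self):
        with pytest.raises(ValueError, match="v0"):
            median_rescale(_table([[0.0], [0.0], [1.0]]))


class TestInverseNormal:
    def test_blom_values_for_n3(self):
        # Phi^{-1}((rank-3/8)/(3+1/4)) for ranks 1..3
        expect = stats.norm.ppf([(1 - 0.375) / 3.25, 0.5, (3 - 0.375) / 3.25])
        np.testing.assert_allclose(
            inverse_normal_transform(np.array([10.0, 20.0, 30.0])), expect,
            atol=1e-12)
        # high-precision evaluation of the Blom formula at n=3, rank 1:
        # Phi^{-1}(0.625/3.25) = -0.86942...
        np.testing.assert_allclose(expect[0], -0.8694238, atol=5e-7)

    def test_monotone_invariance_and_median_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=31)
        a = inverse_normal_transform(x)
        b = inverse_normal_transform(np.exp(3 * x))  # strictly monotone map
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert abs(np.median(a)) < 1e-12

    def test_ties_get_equal_outputs(self):
        out = inverse_normal_transform(np.array([1.0, 1.0, 2.0, 3.0]))
        assert out[0] == out[1]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inverse_normal_transform(np.ones(5))


class TestShapiroScreen:
    def test_int_of_continuous_variable_passes(self):
        rng = np.random.default_rng(1)
        t = int_table(_table(rng.lognormal(size=(100, 1))))
        kept, rep = shapiro_screen(t)
        assert kept.variable_ids == ["v0"]
        assert rep.shapiro_p["v0"] > 0.05

    def test_massive_ties_removed(self):
        x = np.concatenate([np.zeros(90), np.arange(1, 11.0)])
        t = int_table(_table(x[:, None]))
        kept, rep = shapiro_screen(t)
        assert kept.n_variables == 0
        assert rep.shapiro_p["v0"] < 0.05

    def test_alpha_zero_removes_nothing(self):
        x = np.concatenate([np.zeros(90), np.arange(1, 11.0)])
        t = int_table(_table(x[:, None]))
        kept, _ = shapiro_screen(t, alpha=0.0)
        assert kept.n_variables == 1


class TestResidualAdjust:
    def _meta(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return SampleMetadata(pd.DataFrame({
            "gender": rng.choice(["F", "M"], n),
            "total_kcal": rng.uniform(1500, 3000, n),
        }, index=[f"S{i}" for i in range(n)]))

    def test_output_standardized_and_orthogonal_to_covariates(self):
        n = 50
        meta = self._meta(n)
        rng = np.random.default_rng(2)
        diet = _table(rng.normal(size=(n, 3))
                      + 0.01 * meta.data[["total_kcal"]].to_numpy())
        out, _ = residual_adjust(diet, meta)
        vals = out.values
        np.testing.assert_allclose(vals.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(vals.std(axis=0, ddof=1), 1, atol=1e-10)
        kcal = meta.data["total_kcal"].to_numpy()
        kcal_c = kcal - kcal.mean()
        g = pd.factorize(meta.data["gender"])[0].astype(float)
        g_c = g - g.mean()
        assert np.abs(vals.T @ kcal_c / np.linalg.norm(kcal_c)).max() < 1e-8
        assert np.abs(vals.T @ g_c).max() < 1e-8

    def test_fully_collinear_variable_dropped_with_warning(self):
        n = 30
        meta = self._meta(n)
        diet_vals = np.column_stack([
            2.0 * meta.data["total_kcal"].to_numpy(),
            np.random.default_rng(3).normal(size=n),
        ])
        with pytest.warns(UserWarning, match="v0"):
            out, rep = residual_adjust(_table(diet_vals), meta)
        assert out.variable_ids == ["v1"]
        assert not rep.kept("v0")

    def test_idempotent(self):
        n = 40
        meta = self._meta(n, seed=4)
        diet = _table(np.random.default_rng(5).normal(size=(n, 4)))
        once, _ = residual_adjust(diet, meta)
        twice, _ = residual_adjust(once, meta)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_permutation_equivariance(self):
        n = 25
        meta = self._meta(n, seed=6)
        diet = _table(np.random.default_rng(7).normal(size=(n, 2)))
        out, _ = residual_adjust(diet, meta)
        perm = np.random.default_rng(8).permutation(n)
        ids = [diet.sample_ids[i] for i in perm]
        out_p, _ = residual_adjust(diet.select_samples(ids),
                                   meta.select_samples(ids))
        np.testing.assert_allclose(out_p.data.loc[diet.sample_ids].values,
                                   out.values, atol=1e-10)


class TestDedup:
    def test_single_cluster_keeps_one(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=200)
        X = np.column_stack([base + rng.normal(scale=0.05, size=200)
                             for _ in range(3)])
        out, rep = dedup_correlated(_table(X), rho=0.9)
        assert out.n_variables == 1
        assert len(set(rep.representative.values())) == 1

    def test_uncorrelated_unchanged(self):
        X = np.random.default_rng(10).normal(size=(100, 4))
        out, _ = dedup_correlated(_table(X), rho=0.9)
        assert out.n_variables == 4

    def test_chain_component_representative_is_middle(self):
        # A-B and B-C strongly linked, A-C weaker: one component, B is the
        # medoid by mean Spearman
        rng = np.random.default_rng(11)
        n = 400
        b = rng.normal(size=n)
        a = b + rng.normal(scale=0.30, size=n)
        c = -0.0 + b + rng.normal(scale=0.30, size=n) * -1
        X = np.column_stack([a, b, c])
        t = FeatureTable(pd.DataFrame(
            X, index=[f"S{i}" for i in range(n)], columns=["A", "B", "C"]))
        from scipy.stats import spearmanr
        corr = spearmanr(X).statistic
        assert corr[0, 1] > 0.9 and corr[1, 2] > 0.9  # construction holds
        out, rep = dedup_correlated(t, rho=0.9)
        assert out.variable_ids == ["B"]
        assert rep.representative["A"] == "B"

    def test_planted_blocks_collapse_to_one_each(self):
        from triomix.simulate import simulate_diet
        diet, meta, truth = simulate_diet(n=500, k=30, seed=12)
        out, rep = dedup_correlated(diet, rho=0.9)
        for block, members in truth.diet_blocks.items():
            survivors = [v for v in members if v in out.variable_ids]
            assert len(survivors) == 1, f"block {block}: {survivors}"


def test_full_diet_chain_outputs_normal_standardized(metadata):
    rng = np.random.default_rng(13)
    n = 12
    diet = FeatureTable(pd.DataFrame(
        rng.lognormal(size=(n, 5)), index=[f"S{i}" for i in range(n)],
        columns=[f"d{j}" for j in range(5)]))
    out, rep = preprocess_diet(diet, metadata)
    assert out.n_variables >= 4  # INT'd continuous vars pass the screen
    np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-9)
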