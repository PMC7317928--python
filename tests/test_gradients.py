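"""Selection-gradient estimation against independent OLS oracles."""

import numpy as np
import pytest

from conftest import brute_force_ols
from stabsel.data_model import DataError, relative_fitness
from stabsel.gradients import (
    GradientSet,
    cross_sex_design,
    cross_sex_model,
    fit_gradients,
    gradient_correlation,
    linear_gradients,
    quadratic_design,
    quadratic_gradients,
)


class TestLinearGradients:
    def test_constant_fitness_gives_zero_beta_and_r2(self, rng):
        Z = rng.standard_normal((50, 4))
        beta, r2 = linear_gradients(Z, np.ones(50))
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)
        assert r2 == 0.0

    def test_matches_normal_equations_on_small_table(self, rng):
        Z = rng.standard_normal((6, 2))
        w = rng.standard_normal(6) + 1
        beta, _ = linear_gradients(Z, w)
        X = np.column_stack([np.ones(6), Z])
        np.testing.assert_allclose(beta, brute_force_ols(X, w)[1:], atol=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        Z = rng.standard_normal((80, 5))
        w = rng.exponential(size=80)
        w /= w.mean()
        beta, r2 = linear_gradients(Z, w)
        fit = sm.OLS(w, sm.add_constant(Z)).fit()
        np.testing.assert_allclose(beta, fit.params[1:], atol=1e-10)
        np.testing.assert_allclose(r2, fit.rsquared, atol=1e-10)

    def test_recovers_simulated_directional_selection(self, rng):
        n = 5000
        Z = rng.standard_normal((n, 3))
        w = 1 + 0.3 * Z[:, 0] + rng.standard_normal(n)
        beta, _ = linear_gradients(Z, w)
        se = 1 / np.sqrt(n)  # noise sd 1, standardized predictor
        assert abs(beta[0] - 0.3) < 3 * se

    def test_collinear_columns_are_named(self, rng):
        Z = rng.standard_normal((30, 2))
        Z = np.column_stack([Z, Z[:, 0] + Z[:, 1]])
        with pytest.raises(DataError, match="collinear"):
            linear_gradients(Z, rng.standard_normal(30))


class TestQuadraticGradients:
    def test_diagonal_is_doubled_squared_coefficient(self, rng):
        Z = rng.standard_normal((60, 3))
        w = rng.standard_normal(60) + 1
        gamma, _ = quadratic_gradients(Z, w)
        X, terms = quadratic_design(Z, ["a", "b", "c"])
        raw = brute_force_ols(X, w)[1:]
        quad_idx = [k for k, t in enumerate(terms) if t.kind == "quadratic"]
        np.testing.assert_allclose(np.diag(gamma),
                                   2 * raw[quad_idx], atol=1e-10)

    def test_off_diagonals_enter_as_estimated(self, rng):
        Z = rng.standard_normal((60, 3))
        w = rng.standard_normal(60) + 1
        gamma, _ = quadratic_gradients(Z, w)
        X, terms = quadratic_design(Z, ["a", "b", "c"])
        raw = brute_force_ols(X, w)[1:]
        cross = {(t.trait_1, t.trait_2): raw[k] for k, t in enumerate(terms)
                 if t.kind == "correlational"}
        np.testing.assert_allclose(gamma[0, 1], cross[("a", "b")], atol=1e-10)
        np.testing.assert_allclose(gamma[1, 2], cross[("b", "c")], atol=1e-10)

    def test_constant_fitness_gives_zero_gamma(self, rng):
        Z = rng.standard_normal((80, 3))
        gamma, r2 = quadratic_gradients(Z, np.ones(80))
        np.testing.assert_allclose(gamma, 0.0, atol=1e-12)
        assert r2 == 0.0

    def test_doubled_gamma_recovers_generating_curvature(self, rng):
        # w = 1 - 0.5 z1^2: the curvature of the surface is -1.0, which
        # the raw regression coefficient (-0.5) understates by half
        n = 20_000
        Z = rng.standard_normal((n, 2))
        w = 1 - 0.5 * Z[:, 0] ** 2 + 0.1 * rng.standard_normal(n)
        gamma, _ = quadratic_gradients(Z, w)
        assert abs(gamma[0, 0] - (-1.0)) < 0.02
        assert abs(gamma[0, 1]) < 0.02

    def test_gamma_is_exactly_symmetric(self, rng):
        Z = rng.standard_normal((100, 4))
        gamma, _ = quadratic_gradients(Z, rng.standard_normal(100))
        np.testing.assert_array_equal(gamma, gamma.T)

    def test_quadratic_r2_at_least_linear_r2(self, trial_dataset):
        from stabsel.data_model import standardize

        dataset, _ = trial_dataset
        w = relative_fitness(dataset.success).w
        gs = fit_gradients(standardize(dataset.male_traits).z, w)
        assert gs.r2_quadratic >= gs.r2_linear


class TestCrossSexModel:
    def test_matches_explicit_design_matrix_oracle(self, rng):
        n, p = 70, 2  # 15-parameter two-sex model
        Zm = rng.standard_normal((n, p))
        Zf = rng.standard_normal((n, p))
        w = rng.standard_normal(n) + 1
        set_m, set_f, inter = cross_sex_model(Zm, Zf, w, ["a", "b"], ["a", "b"])
        X, terms = cross_sex_design(Zm, Zf, ["a", "b"], ["a", "b"])
        raw = brute_force_ols(X, w)[1:]
        by_label = {t.label(): raw[k] for k, t in enumerate(terms)}
        np.testing.assert_allclose(
            set_m.gamma[0, 0], 2 * by_label["quadratic:male:a"], atol=1e-10)
        np.testing.assert_allclose(
            set_f.gamma[0, 1], by_label["correlational:female:a:female:b"],
            atol=1e-10)
        np.testing.assert_allclose(
            inter.values[1, 0], by_label["cross_sex:female:b:male:a"],
            atol=1e-10)

    def test_recovers_single_cross_sex_term(self, rng):
        n = 20_000
        Zm = rng.standard_normal((n, 5))
        Zf = rng.standard_normal((n, 5))
        w = 1 + 0.2 * Zm[:, 0] * Zf[:, 3] + 0.5 * rng.standard_normal(n)
        _, _, inter = cross_sex_model(Zm, Zf, w)
        se = 0.5 / np.sqrt(n)
        assert abs(inter.values[3, 0] - 0.2) < 3 * se
        others = inter.values.copy()
        others[3, 0] = 0.0
        assert np.abs(others).max() < 4 * se

    def test_null_fitness_leaves_all_entries_near_zero(self, rng):
        n = 5000
        Zm = rng.standard_normal((n, 3))
        Zf = rng.standard_normal((n, 3))
        w = 1 + rng.standard_normal(n)
        _, _, inter = cross_sex_model(Zm, Zf, w)
        assert np.abs(inter.values).max() < 4 / np.sqrt(n)

    def test_too_few_pairs_reports_required_minimum(self, rng):
        Zm = rng.standard_normal((40, 5))
        Zf = rng.standard_normal((40, 5))
        with pytest.raises(DataError, match="66"):
            cross_sex_model(Zm, Zf, np.ones(40))


class TestGradientCorrelation:
    def _sets(self, rng, p=5):
        def one():
            beta = rng.standard_normal(p)
            g = rng.standard_normal((p, p))
            return GradientSet(beta, 0.5 * (g + g.T), 0.1, 0.2, 100,
                               [f"t{j}" for j in range(p)])
        return one(), one()

    def test_class_sizes_for_five_traits_per_sex(self, rng):
        sets = self._sets(rng)
        report = gradient_correlation(sets, sets)
        assert report["linear"]["n"] == 10
        assert report["quadratic"]["n"] == 10
        assert report["correlational"]["n"] == 20

    def test_self_correlation_is_one(self, rng):
        sets = self._sets(rng)
        report = gradient_correlation(sets, sets)
        for cls in report.values():
            assert cls["r"] == pytest.approx(1.0)

    def test_matches_direct_pearson_on_noisy_copy(self, rng):
        from scipy.stats import pearsonr

        a = self._sets(rng)
        b = (GradientSet(a[0].beta + 0.01 * rng.standard_normal(5),
                         a[0].gamma, 0.1, 0.2, 100, a[0].trait_names),
             a[1])
        report = gradient_correlation(a, b)
        lin_a = np.concatenate([a[0].beta, a[1].beta])
        lin_b = np.concatenate([b[0].beta, b[1].beta])
        r, p = pearsonr(lin_a, lin_b)
        assert report["linear"]["r"] == pytest.approx(r)
        assert report["linear"]["p"] == pytest.approx(p)
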