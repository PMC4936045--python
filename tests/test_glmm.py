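"""Mixed-model likelihood, Laplace approximation, AICc machinery."""

import numpy as np
import pandas as pd
import pytest

from bearshield import (
    ModelSpec,
    aicc,
    akaike_weights,
    fit_model,
    joint_mode,
    laplace_marginal_loglik,
    logistic_loglik,
)
from bearshield.quadrature import aghq_marginal_loglik, fit_aghq


def _toy_table(seed=1, n_groups=8, n_per=20, beta=(-0.3, 0.8), sigma=0.5, n_years=1):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_per)
    yr = rng.integers(0, n_years, len(g))
    x = rng.normal(size=len(g))
    u = rng.normal(0.0, sigma, n_groups)
    uy = rng.normal(0.0, 0.3, n_years) if n_years > 1 else np.zeros(1)
    eta = beta[0] + beta[1] * x + u[g] + uy[yr]
    y = (rng.random(len(g)) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"is_used": y, "x": x, "bear_id": g, "year": yr, "survival": 0})


SPEC1 = ModelSpec(label="single", fixed_terms=("x",), random_factors=("bear_id",))


class TestLoglik:
    def test_null_model_closed_form(self):
        table = _toy_table()
        n = len(table)
        val = logistic_loglik(np.zeros(2), {}, table, SPEC1)
        assert val == pytest.approx(-n * np.log(2.0), abs=1e-10)

    def test_large_eta_no_overflow(self):
        table = pd.DataFrame(
            {"is_used": [1], "x": [1.0], "bear_id": [0], "year": [0], "survival": [0]}
        )
        val = logistic_loglik(np.array([0.0, 50.0]), {}, table, SPEC1)
        assert np.isfinite(val) and val == pytest.approx(0.0, abs=1e-10)

    def test_matches_per_row_summation(self):
        table = _toy_table(seed=3)
        rng = np.random.default_rng(0)
        beta = rng.normal(size=2)
        u = {"bear_id": rng.normal(0, 0.4, 8)}
        val = logistic_loglik(beta, u, table, SPEC1)
        direct = 0.0
        for _, row in table.iterrows():
            eta = beta[0] + beta[1] * row["x"] + u["bear_id"][int(row["bear_id"])]
            direct += row["is_used"] * eta - np.log1p(np.exp(eta))
        assert val == pytest.approx(direct, abs=1e-10)


class TestJointMode:
    def test_vanishing_variance_pins_mode_at_zero(self):
        table = _toy_table(seed=4)
        u, H = joint_mode(np.array([0.1, 0.5]), 1e-9, 1e-9, table, SPEC1)
        assert np.max(np.abs(u["bear_id"])) < 1e-5

    def test_balanced_outcomes_give_zero_mode(self):
        x = np.tile(np.linspace(-1, 1, 10), 2)  # same covariates for the 0s and 1s
        table = pd.DataFrame(
            {
                "is_used": np.repeat([0, 1], 10),
                "x": x,
                "bear_id": 0,
                "year": 0,
                "survival": 0,
            }
        )
        u, _ = joint_mode(np.zeros(2), 0.5, 0.5, table, SPEC1)
        assert u["bear_id"][0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search(self):
        table = _toy_table(seed=5, n_groups=3, n_per=10)
        beta = np.array([0.0, 0.6])
        s2 = 0.4
        u, _ = joint_mode(beta, s2, s2, table, SPEC1)

        def penalized(uvec):
            val = logistic_loglik(beta, {"bear_id": uvec}, table, SPEC1)
            return val - 0.5 * np.sum(uvec**2) / s2

        from scipy.optimize import minimize

        res = minimize(lambda v: -penalized(v), np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12})
        np.testing.assert_allclose(u["bear_id"], res.x, atol=1e-6)


class TestLaplace:
    def test_fixed_effects_limit(self):
        table = _toy_table(seed=6)
        beta = np.array([0.2, 0.4])
        lap = laplace_marginal_loglik(beta, 1e-10, 1e-10, table, SPEC1)
        plain = logistic_loglik(beta, {}, table, SPEC1)
        assert lap == pytest.approx(plain, abs=1e-6)

    def test_agrees_with_quadrature_at_fixed_parameters(self):
        table = _toy_table(seed=7)
        beta = np.array([-0.2, 0.7])
        sigma = 0.6
        lap = laplace_marginal_loglik(beta, sigma**2, sigma**2, table, SPEC1)
        X = np.column_stack([np.ones(len(table)), table["x"]])
        agq = aghq_marginal_loglik(
            beta, sigma, X, table["is_used"].to_numpy(float), table["bear_id"].to_numpy()
        )
        assert lap == pytest.approx(agq, abs=0.05)

    def test_row_duplication_doubles_data_term(self):
        table = _toy_table(seed=8, n_groups=4, n_per=12)
        beta = np.array([0.1, 0.3])
        u, _ = joint_mode(beta, 1e-10, 1e-10, table, SPEC1)
        base = logistic_loglik(beta, u, table, SPEC1)
        doubled = logistic_loglik(
            beta, u, pd.concat([table, table], ignore_index=True), SPEC1
        )
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)


class TestFit:
    def test_null_data_recovers_null(self):
        rng = np.random.default_rng(9)
        n = 1200
        table = pd.DataFrame(
            {
                "is_used": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
                "bear_id": rng.integers(0, 10, n),
                "year": rng.integers(0, 4, n),
                "survival": 0,
            }
        )
        fit = fit_model(table, ModelSpec(label="m", fixed_terms=("x",)))
        for term in ("(intercept)", "x"):
            assert abs(fit.beta[term]) < 3 * fit.se[term]
        assert fit.sigma2_id < 0.02 and fit.sigma2_year < 0.02

    def test_matches_plain_logistic_without_random_factors(self):
        import statsmodels.api as sm

        table = _toy_table(seed=10)
        spec = ModelSpec(label="fe", fixed_terms=("x",), random_factors=())
        fit = fit_model(table, spec)
        X = np.column_stack([np.ones(len(table)), table["x"]])
        ref = sm.GLM(table["is_used"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert fit.beta["(intercept)"] == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.beta["x"] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert fit.se["x"] == pytest.approx(ref.bse[1], abs=1e-4)

    def test_matches_lme4_crossed_reference(self, tmp_path):
        """Independent cross-check of the crossed-intercepts fit against glmer."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        table = _toy_table(seed=7, n_groups=12, n_per=40, n_years=6)
        spec = ModelSpec(label="crossed", fixed_terms=("x",))
        fit = fit_model(table, spec)
        csv = tmp_path / "d.csv"
        table.rename(columns={"is_used": "y", "bear_id": "b", "year": "yr"}).to_csv(
            csv, index=False
        )
        script = (
            f'd <- read.csv("{csv}"); d$b <- factor(d$b); d$yr <- factor(d$yr); '
            "suppressMessages(library(lme4)); "
            "m <- glmer(y ~ x + (1|b) + (1|yr), data=d, family=binomial); "
            'cat(fixef(m), unlist(VarCorr(m)), logLik(m), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, s2b, s2y, ll = map(float, out.stdout.split())
        assert fit.beta["(intercept)"] == pytest.approx(b0, abs=2e-3)
        assert fit.beta["x"] == pytest.approx(b1, abs=2e-3)
        assert fit.sigma2_id == pytest.approx(s2b, abs=5e-3)
        assert fit.sigma2_year == pytest.approx(s2y, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_rank_deficiency_names_aliased_terms(self):
        table = _toy_table(seed=11)
        table["x2"] = 2.0 * table["x"]
        spec = ModelSpec(label="bad", fixed_terms=("x", "x2"), random_factors=("bear_id",))
        with pytest.raises(ValueError, match="aliased"):
            fit_model(table, spec)

    def test_loglik_invariant_under_affine_reparametrization(self):
        table = _toy_table(seed=12)
        fit1 = fit_model(table, SPEC1)
        table2 = table.copy()
        table2["x"] = (table2["x"] - 5.0) / 2.0
        fit2 = fit_model(table2, SPEC1)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
        assert fit2.beta["x"] == pytest.approx(2.0 * fit1.beta["x"], abs=1e-4)


class TestQuadratureOracle:
    def test_sigma_zero_reduces_to_plain_loglik(self):
        table = _toy_table(seed=13)
        X = np.column_stack([np.ones(len(table)), table["x"]])
        y = table["is_used"].to_numpy(float)
        beta = np.array([0.3, -0.4])
        eta = X @ beta
        plain = float(np.sum(y * eta - np.logaddexp(0, eta)))
        assert aghq_marginal_loglik(beta, 0.0, X, y, table["bear_id"].to_numpy()) == pytest.approx(
            plain, abs=1e-12
        )

    def test_node_count_converged(self):
        table = _toy_table(seed=14)
        X = np.column_stack([np.ones(len(table)), table["x"]])
        y = table["is_used"].to_numpy(float)
        g = table["bear_id"].to_numpy()
        beta = np.array([-0.1, 0.6])
        a = aghq_marginal_loglik(beta, 0.7, X, y, g, n_nodes=32)
        b = aghq_marginal_loglik(beta, 0.7, X, y, g, n_nodes=64)
        assert a == pytest.approx(b, abs=1e-8)


class TestAicc:
    def test_closed_form_value(self):
        assert aicc(-100.0, 3, 100) == pytest.approx(206.25)

    def test_approaches_aic_for_large_n(self):
        val = aicc(-500.0, 5, 10_000_000)
        assert val == pytest.approx(-2 * -500.0 + 2 * 5, abs=1e-3)

    def test_matches_direct_formula_on_random_inputs(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            ll = rng.uniform(-1000, -10)
            k = int(rng.integers(1, 20))
            n = int(rng.integers(k + 2, 5000))
            expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert aicc(ll, k, n) == pytest.approx(expected, rel=1e-12)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_single_model_weight_one(self):
        np.testing.assert_allclose(akaike_weights([123.4]), [1.0])

    def test_equal_aicc_split_evenly(self):
        np.testing.assert_allclose(akaike_weights([100.0, 100.0]), [0.5, 0.5])

    def test_two_unit_gap(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.731, abs=0.001)
        assert w[1] == pytest.approx(0.269, abs=0.001)

    def test_shift_invariant_and_normalized(self):
        rng = np.random.default_rng(16)
        vals = rng.uniform(200, 260, 9)
        w1 = akaike_weights(vals)
        w2 = akaike_weights(vals + 57.3)
        np.testing.assert_allclose(w1, w2, atol=1e-12)
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)
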