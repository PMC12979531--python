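"""GLMM engine: closed forms, GLM oracles, parameter recovery, diagnostics,
and an independent mixed-model cross-check through Rscript/glmmTMB."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pigeonpop import (FitOptions, ModelSpec, compare_models, fit_glmm,
                       wald_table, zero_inflation_check)
from pigeonpop.glmm import EstimabilityError


def nb_mixed_data(seed, n_groups=200, per_group=10, beta0=1.0, beta1=0.5,
                  theta=2.0, sigma=0.5):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per_group)
    u = rng.normal(0.0, sigma, n_groups)
    x = rng.integers(0, 2, g.size).astype(float)
    mu = np.exp(beta0 + beta1 * x + u[g])
    y = rng.poisson(rng.gamma(theta, mu / theta))
    return pd.DataFrame({"count": y, "x": x, "trial": g})


class TestClosedForms:
    def test_poisson_intercept_only_is_log_mean(self):
        df = pd.DataFrame({"count": [5] * 50})
        fit = fit_glmm(df, ModelSpec("count", [], [], family="poisson"))
        assert fit.beta["(Intercept)"] == pytest.approx(np.log(5.0), abs=1e-8)

    def test_sigma_zero_matches_poisson_glm_irls_oracle(self):
        df = nb_mixed_data(0, theta=1e6, sigma=0.0)
        fit = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="poisson"),
                       FitOptions(fix_sigma={"trial": 0.0}))
        X = np.column_stack([np.ones(len(df)), df["x"]])
        oracle = sm.GLM(df["count"], X, family=sm.families.Poisson()).fit()
        assert np.abs(fit.beta.to_numpy() - oracle.params).max() < 1e-6
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_sigma_zero_negbin_matches_statsmodels_at_fitted_theta(self):
        df = nb_mixed_data(1, theta=1.5, sigma=0.0, n_groups=100)
        fit = fit_glmm(df, ModelSpec("count", ["x"], [], family="negbin"))
        X = np.column_stack([np.ones(len(df)), df["x"]])
        oracle = sm.GLM(df["count"], X,
                        family=sm.families.NegativeBinomial(
                            alpha=1.0 / fit.theta)).fit()
        assert np.abs(fit.beta.to_numpy() - oracle.params).max() < 1e-6

    def test_nb_degenerates_to_poisson_at_huge_theta(self):
        df = nb_mixed_data(2, theta=1e6, sigma=0.4, n_groups=80)
        spec_p = ModelSpec("count", ["x"], ["trial"], family="poisson")
        spec_nb = ModelSpec("count", ["x"], ["trial"], family="negbin")
        fp = fit_glmm(df, spec_p)
        fnb = fit_glmm(df, spec_nb, FitOptions(fix_theta=1e6))
        assert np.abs(fp.beta.to_numpy() - fnb.beta.to_numpy()).max() < 1e-4


class TestRecoveryAndInference:
    def test_parameter_recovery_within_3se(self):
        df = nb_mixed_data(3)
        fit = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="negbin"))
        assert fit.converged and not fit.singular
        assert abs(fit.beta["(Intercept)"] - 1.0) < 3 * fit.se["(Intercept)"]
        assert abs(fit.beta["x"] - 0.5) < 3 * fit.se["x"]
        assert fit.theta == pytest.approx(2.0, rel=0.3)
        assert fit.sigma["trial"] == pytest.approx(0.5, rel=0.3)

    def test_wald_table_matches_normal_cdf_oracle(self):
        from scipy.stats import norm
        df = nb_mixed_data(4, n_groups=50)
        fit = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="negbin"))
        tab = wald_table(fit)
        for name in fit.beta.index:
            z = fit.beta[name] / fit.se[name]
            assert tab.loc[name, "z"] == pytest.approx(z)
            assert tab.loc[name, "p"] == pytest.approx(2 * norm.sf(abs(z)))

    def test_singular_flag_on_groupless_data(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"count": rng.poisson(3.0, 600),
                           "trial": np.repeat(np.arange(60), 10)})
        fit = fit_glmm(df, ModelSpec("count", [], ["trial"], family="poisson"))
        assert fit.singular
        assert fit.sigma["trial"] < 1e-3

    def test_rank_deficient_design_raises_with_alias(self):
        df = pd.DataFrame({"count": [1, 2, 3, 4],
                           "a": ["x", "x", "y", "y"],
                           "b": ["u", "u", "v", "v"]})
        with pytest.raises(EstimabilityError, match=r"b\[v\]"):
            fit_glmm(df, ModelSpec("count", ["a", "b"], [], family="poisson"))

    def test_empty_and_invalid_data_rejected(self):
        with pytest.raises(ValueError):
            fit_glmm(pd.DataFrame({"count": []}), ModelSpec("count", [], []))
        with pytest.raises(ValueError):
            fit_glmm(pd.DataFrame({"count": [-1, 2]}),
                     ModelSpec("count", [], [], family="poisson"))


class TestModelComparison:
    def test_identical_fits_give_zero(self):
        df = nb_mixed_data(6, n_groups=40)
        fit = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="negbin"))
        daic, chi2, dof, p = compare_models(fit, fit)
        assert daic == 0.0 and chi2 == 0.0 and dof == 0 and p == 1.0

    def test_nb_beats_poisson_on_overdispersed_counts(self):
        df = nb_mixed_data(7, theta=0.5, sigma=0.0, n_groups=100)
        fp = fit_glmm(df, ModelSpec("count", ["x"], [], family="poisson"))
        fnb = fit_glmm(df, ModelSpec("count", ["x"], [], family="negbin"))
        daic, chi2, dof, p = compare_models(fnb, fp)
        assert fnb.aic < fp.aic
        assert chi2 > 0 and dof == 1 and p < 1e-6

    def test_theta_lrt_calibrated_on_poisson_data(self):
        # Poisson truth: the NB-vs-Poisson LRT (naive chi2(1) reference,
        # conservative at the theta boundary) rejects rarely
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            df = pd.DataFrame({"count": rng.poisson(3.0, 300)})
            fp = fit_glmm(df, ModelSpec("count", [], [], family="poisson"))
            fnb = fit_glmm(df, ModelSpec("count", [], [], family="negbin"))
            _d, _c, _df, p = compare_models(fnb, fp)
            hits += p < 0.05
        assert hits <= 10   # >= 90% non-significant

    def test_different_n_rejected(self):
        a = fit_glmm(pd.DataFrame({"count": [1, 2, 3]}),
                     ModelSpec("count", [], [], family="poisson"))
        b = fit_glmm(pd.DataFrame({"count": [1, 2]}),
                     ModelSpec("count", [], [], family="poisson"))
        with pytest.raises(ValueError):
            compare_models(a, b)


class TestZeroInflation:
    def test_well_specified_model_ratio_near_one(self):
        df = nb_mixed_data(8, beta0=0.3, n_groups=100)
        fit = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="negbin"))
        ratio, p = zero_inflation_check(fit, n_sims=300, seed=0)
        assert 0.9 <= ratio <= 1.1
        assert p > 0.05

    def test_structural_zeros_detected(self):
        # with a high baseline rate the NB law itself predicts almost no
        # zeros, so injected structural zeros are unambiguous
        rng = np.random.default_rng(9)
        df = nb_mixed_data(9, beta0=2.0, theta=5.0, sigma=0.2, n_groups=100)
        zero_out = rng.random(len(df)) < 0.3
        df.loc[zero_out, "count"] = 0
        fit = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="negbin"))
        ratio, p = zero_inflation_check(fit, n_sims=300, seed=1)
        assert ratio > 1.0
        assert p < 0.05

    def test_all_positive_counts_give_ratio_below_one(self):
        df = pd.DataFrame({"count": np.full(400, 1),
                           "trial": np.repeat(np.arange(40), 10)})
        fit = fit_glmm(df, ModelSpec("count", [], ["trial"], family="poisson"))
        ratio, _p = zero_inflation_check(fit, n_sims=200, seed=2)
        assert ratio < 1.0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_mixed_nb_fit_cross_checked_against_glmmtmb(tmp_path):
    """Independent oracle: glmmTMB (Laplace NB2 GLMM) on a tiny fixture."""
    df = nb_mixed_data(7, n_groups=40, per_group=8, beta0=0.8, beta1=0.6,
                       theta=1.5, sigma=0.4)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    fit = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="negbin"))
    r_code = f"""
    suppressMessages(library(glmmTMB))
    d <- read.csv("{csv}")
    m <- glmmTMB(count ~ x + (1|trial), data=d, family=nbinom2)
    cat(fixef(m)$cond, sigma(m), sqrt(VarCorr(m)$cond$trial[1,1]),
        as.numeric(logLik(m)), sep=",")
    """
    out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    b0, b1, theta, sigma, ll = map(float, out.stdout.strip().split(","))
    assert fit.beta["(Intercept)"] == pytest.approx(b0, abs=2e-3)
    assert fit.beta["x"] == pytest.approx(b1, abs=2e-3)
    assert fit.theta == pytest.approx(theta, rel=0.01)
    assert fit.sigma["trial"] == pytest.approx(sigma, rel=0.01)
    assert fit.loglik == pytest.approx(ll, abs=1e-2)
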