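"""Hierarchical RSF estimation: oracle equivalence, weights, prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from elkrsf.inference import (
    RSFModelSpec,
    design_matrix,
    fit_hierarchical_rsf,
    fit_weighted_logistic,
    posterior_summary,
    predict_relative_use,
)
from elkrsf.synthetic import simulate_used_available


@pytest.fixture(scope="module")
def toy_table():
    """200-row single-individual table with known logistic structure."""
    rng = np.random.default_rng(21)
    df = pd.DataFrame(rng.standard_normal((200, 3)), columns=["de", "ml", "wf"])
    lp = 0.4 * df.de - 0.6 * df.ml + 0.2 * df.wf
    df["used"] = (rng.uniform(size=200) < 1 / (1 + np.exp(-lp))).astype(int)
    df["weight"] = 1.0
    df["individual_id"] = "a"
    return df


def test_map_equals_logistic_mle(toy_table):
    """Unweighted flat-prior MAP reproduces the IRLS maximum likelihood fit."""
    import statsmodels.api as sm

    spec = RSFModelSpec(random_slopes=False, fixed_prior_scale=None)
    post = fit_hierarchical_rsf(toy_table, spec, method="map", draws=0)
    X = design_matrix(toy_table, spec.terms)
    ref = sm.GLM(toy_table["used"].to_numpy(), X,
                 family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(post.beta_map, ref.params, atol=1e-3)


def test_weight_halving_invariance(toy_table):
    """Duplicating available rows at half weight leaves the MAP unchanged."""
    t = toy_table.copy()
    t.loc[t.used == 0, "weight"] = 1000.0
    spec = RSFModelSpec(random_slopes=False, fixed_prior_scale=None)
    base = fit_hierarchical_rsf(t, spec, method="map", draws=0).beta_map

    avail = t[t.used == 0].copy()
    t2 = pd.concat([t, avail], ignore_index=True)
    t2.loc[t2.used == 0, "weight"] = 500.0
    dup = fit_hierarchical_rsf(t2, spec, method="map", draws=0).beta_map
    np.testing.assert_allclose(base, dup, atol=1e-6)


def test_hierarchical_fit_recovers_truth(model_table):
    """Posterior means sit within 2 posterior SDs of the generating values."""
    table, gamma = model_table
    post = fit_hierarchical_rsf(table, RSFModelSpec(), method="laplace",
                                draws=200, seed=5)
    truth = {"de": 0.2, "ml": -0.1, "wf": 0.3, "de:ml": -0.1, "de:wf": 0.0}
    for i, t in enumerate(post.terms):
        if t == "intercept":
            continue
        d = post.beta_draws[:, i]
        assert abs(d.mean() - truth[t]) < 2 * d.std(), t
    assert (post.sigma_draws.mean(axis=0) > 0).all()


def test_hierarchical_centering(model_table):
    """Across individuals, coefficient draws centre on the population draw."""
    table, _ = model_table
    post = fit_hierarchical_rsf(table, RSFModelSpec(), method="laplace",
                                draws=200, seed=6)
    gbar = post.gamma_draws.mean(axis=(0, 1))  # average over draws and elk
    bbar = post.beta_draws.mean(axis=0)
    for i, t in enumerate(post.terms):
        if t == "intercept":
            continue
        # Monte-Carlo error of the across-individual mean
        tol = 3 * post.beta_draws[:, i].std() / np.sqrt(len(post.individuals)) + 0.05
        assert abs(gbar[i] - bbar[i]) < tol, t


def test_non_finite_covariates_rejected(toy_table):
    t = toy_table.copy()
    t.loc[0, "de"] = np.nan
    with pytest.raises(ValueError):
        fit_hierarchical_rsf(t, RSFModelSpec(random_slopes=False), method="map")


def test_mcmc_mode_runs_small():
    table, _ = simulate_used_available(n_individuals=5, n_used=60, ratio=5, seed=40)
    post = fit_hierarchical_rsf(table, RSFModelSpec(), method="mcmc", draws=100,
                                seed=3, mcmc_walkers=24, mcmc_warmup=60, mcmc_steps=60)
    assert post.n_draws == 100
    summ = post.summary()
    assert np.isfinite(summ["mean"]).all()
    # mean of each parameter lies inside its own 90% interval
    assert (summ["mean"] >= summ["lo90"]).all() and (summ["mean"] <= summ["hi90"]).all()


def test_posterior_summary_closed_form():
    rng = np.random.default_rng(8)
    draws = rng.standard_normal(100_000)
    mean, lo, hi = posterior_summary(draws, 0.90)
    assert lo == pytest.approx(-1.6449, abs=0.02)
    assert hi == pytest.approx(1.6449, abs=0.02)
    assert mean == pytest.approx(0.0, abs=0.02)


def test_posterior_summary_edge_cases():
    mean, lo, hi = posterior_summary(np.full(200, 3.5))
    assert (mean, lo, hi) == (3.5, 3.5, 3.5)
    with pytest.raises(ValueError):
        posterior_summary([])


@settings(max_examples=20, deadline=None)
@given(st.floats(-5, 5))
def test_posterior_summary_shift_equivariance(k):
    rng = np.random.default_rng(17)
    draws = rng.standard_normal(500)
    m0, l0, h0 = posterior_summary(draws)
    m1, l1, h1 = posterior_summary(draws + k)
    assert m1 == pytest.approx(m0 + k, abs=1e-9)
    assert l1 == pytest.approx(l0 + k, abs=1e-9)
    assert h1 == pytest.approx(h0 + k, abs=1e-9)


@pytest.fixture(scope="module")
def fitted():
    table, _ = simulate_used_available(n_individuals=6, n_used=80, ratio=5, seed=50)
    return fit_hierarchical_rsf(table, RSFModelSpec(), method="laplace",
                                draws=100, seed=2)


class TestPredictRelativeUse:
    def test_zero_covariates_give_exp_intercept(self, fitted):
        cov = pd.DataFrame({"de": [0.0], "ml": [0.0], "wf": [0.0]})
        w = predict_relative_use(fitted, cov, level="population")
        b0 = fitted.beta_draws.mean(axis=0)[0]
        assert w[0] == pytest.approx(np.exp(b0))

    def test_relative_use_ratio_is_exp_coefficient(self, fitted):
        cov = pd.DataFrame({"de": [0.0, 1.0], "ml": [0.0, 0.0], "wf": [0.0, 0.0]})
        w = predict_relative_use(fitted, cov, level="population")
        b_de = fitted.beta_draws.mean(axis=0)[1]
        assert w[1] / w[0] == pytest.approx(np.exp(b_de), rel=1e-10)

    def test_monotone_in_de_when_coefficient_positive(self, fitted):
        de = np.linspace(-2, 2, 9)
        cov = pd.DataFrame({"de": de, "ml": 0.0, "wf": 0.0})
        w = predict_relative_use(fitted, cov, level="population")
        b_de = fitted.beta_draws.mean(axis=0)[1]
        diffs = np.diff(w)
        assert (diffs > 0).all() if b_de > 0 else (diffs < 0).all()
        assert (w > 0).all()

    def test_individual_level_uses_individual_coefficients(self, fitted):
        ind = fitted.individuals[0]
        cov = pd.DataFrame({"de": [1.0], "ml": [0.5], "wf": [-0.5]})
        w = predict_relative_use(fitted, cov, level="individual", individual=ind)
        g = fitted.individual_coefficients().loc[ind]
        lp = (g["intercept"] + g["de"] * 1.0 + g["ml"] * 0.5 + g["wf"] * -0.5
              + g["de:ml"] * 0.5 + g["de:wf"] * -0.5)
        assert w[0] == pytest.approx(np.exp(lp))

    def test_unknown_individual_raises(self, fitted):
        cov = pd.DataFrame({"de": [0.0], "ml": [0.0], "wf": [0.0]})
        with pytest.raises(KeyError):
            predict_relative_use(fitted, cov, level="individual", individual="nope")
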