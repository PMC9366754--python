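"""Trade-off metric and nonconsumptive-effect (NCE) models."""

import numpy as np
import pandas as pd
import pytest

from elkrsf.inference import RSFPosterior
from elkrsf.synthetic import simulate_demography
from elkrsf.tradeoff import (
    compute_tradeoff,
    fit_bodyfat_model,
    fit_pregnancy_model,
    tradeoff_quantiles,
)

TERMS = ("intercept", "de", "ml", "wf", "de:ml", "de:wf")


def _posterior_from_coefs(coef_rows: dict[str, dict[str, float]]) -> RSFPosterior:
    """Posterior stub whose per-individual means are given exactly."""
    inds = list(coef_rows)
    gamma = np.array([[coef_rows[i].get(t, 0.0) for t in TERMS] for i in inds])
    p = len(TERMS)
    return RSFPosterior(
        terms=TERMS, slope_terms=TERMS[1:], individuals=inds,
        beta_draws=np.zeros((1, p)), sigma_draws=np.zeros((1, p - 1)),
        gamma_draws=gamma[None, :, :],
        beta_map=np.zeros(p), sigma_map=np.zeros(p - 1), gamma_map=gamma,
    )


def test_worked_tradeoff_value():
    """gDE=0.2, gml=-0.3, gde:ml=-0.1 at q95(DE)=q95(ml)=1.6, q05(ml)=-1.6
    gives exp(-0.416) - exp(1.056) ~ -2.215."""
    # symmetric columns rescaled so the 5th/95th percentiles are exactly +-1.6
    base = np.linspace(-1.0, 1.0, 39)
    table = pd.DataFrame({"de": base, "ml": base, "wf": np.zeros(39)})
    for c in ("de", "ml"):
        table[c] = table[c] * (1.6 / table[c].quantile(0.95))
    post = _posterior_from_coefs({"elk1": {"de": 0.2, "ml": -0.3, "de:ml": -0.1}})
    delta = compute_tradeoff(post, table, predator="ml")
    expected = np.exp(-0.416) - np.exp(1.056)
    assert delta["elk1"] == pytest.approx(expected, abs=1e-12)
    assert delta["elk1"] == pytest.approx(-2.215, abs=1e-3)


def test_zero_risk_response_gives_zero_tradeoff():
    post = _posterior_from_coefs({"e": {"de": 0.7, "ml": 0.0, "de:ml": 0.0,
                                        "wf": 0.4, "de:wf": 0.2}})
    table = pd.DataFrame({"de": np.linspace(-2, 2, 50),
                          "ml": np.linspace(-2, 2, 50),
                          "wf": np.linspace(-2, 2, 50)})
    delta = compute_tradeoff(post, table, predator="ml")
    assert delta["e"] == pytest.approx(0.0, abs=1e-14)


def test_sign_flip_antisymmetry_without_interaction():
    table = pd.DataFrame({"de": np.linspace(-2, 2, 50),
                          "ml": np.linspace(-2, 2, 50),
                          "wf": np.linspace(-2, 2, 50)})
    plus = _posterior_from_coefs({"e": {"de": 0.3, "ml": 0.5}})
    minus = _posterior_from_coefs({"e": {"de": 0.3, "ml": -0.5}})
    d1 = compute_tradeoff(plus, table, predator="ml")["e"]
    d2 = compute_tradeoff(minus, table, predator="ml")["e"]
    assert d1 == pytest.approx(-d2, rel=1e-12)
    assert d1 > 0 > d2


def test_tradeoff_matches_bruteforce_for_every_individual():
    rng = np.random.default_rng(13)
    coefs = {
        f"elk{i}": {t: rng.normal(0, 0.3) for t in TERMS} for i in range(12)
    }
    post = _posterior_from_coefs(coefs)
    table = pd.DataFrame(rng.standard_normal((500, 3)), columns=["de", "ml", "wf"])
    q = tradeoff_quantiles(table)
    delta = compute_tradeoff(post, table, predator="wf")
    for ind, c in coefs.items():
        hi = np.exp(c["de"] * q["de"] + c["wf"] * q["wf_hi"]
                    + c["de:wf"] * q["de"] * q["wf_hi"])
        lo = np.exp(c["de"] * q["de"] + c["wf"] * q["wf_lo"]
                    + c["de:wf"] * q["de"] * q["wf_lo"])
        assert delta[ind] == hi - lo  # exact, machine precision


def test_tradeoff_intercept_flag():
    coefs = {"e": {"intercept": 1.0, "de": 0.2, "ml": -0.3}}
    table = pd.DataFrame(np.random.default_rng(1).standard_normal((100, 3)),
                         columns=["de", "ml", "wf"])
    base = compute_tradeoff(_posterior_from_coefs(coefs), table, "ml")["e"]
    with_icpt = compute_tradeoff(_posterior_from_coefs(coefs), table, "ml",
                                 include_intercept=True)["e"]
    assert with_icpt == pytest.approx(np.exp(1.0) * base, rel=1e-12)


# ---------------------------------------------------------------------------
# NCE models
# ---------------------------------------------------------------------------

def _demo_frame(n=30, seed=0, beta_pred=0.5, beta_lact=-2.0):
    rng = np.random.default_rng(seed)
    pred = rng.standard_normal(n)
    lact = (rng.uniform(size=n) < 0.5).astype(int)
    ifbf = 8.0 + beta_pred * pred + beta_lact * lact + rng.normal(0, 1.5, n)
    preg = (rng.uniform(size=n) < 1 / (1 + np.exp(-(1.0 + 0.3 * pred)))).astype(int)
    return pd.DataFrame({"individual_id": [f"e{i}" for i in range(n)],
                         "tradeoff_ml": pred, "lact": lact,
                         "ifbf": ifbf, "preg": preg})


def test_bodyfat_flat_prior_map_equals_ols():
    import statsmodels.api as sm

    data = _demo_frame(seed=3)
    post = fit_bodyfat_model(data, "ml", seed=1, prior_sd=None)
    X = np.column_stack([np.ones(len(data)), data.tradeoff_ml, data.lact,
                         data.tradeoff_ml * data.lact])
    ols = sm.OLS(data.ifbf.to_numpy(), X).fit()
    np.testing.assert_allclose(post.coef_map, ols.params, atol=1e-10)


def test_pregnancy_flat_prior_map_equals_logistic_mle():
    import statsmodels.api as sm

    data = _demo_frame(n=40, seed=4)
    post = fit_pregnancy_model(data, "ml", seed=1, slope_prior_sd=None)
    X = np.column_stack([np.ones(len(data)), data.tradeoff_ml, data.lact,
                         data.tradeoff_ml * data.lact])
    ref = sm.GLM(data.preg.to_numpy(), X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(post.coef_map, ref.params, atol=1e-3)


def test_bodyfat_relabeling_invariance():
    data = _demo_frame(seed=6)
    a = fit_bodyfat_model(data, "ml", seed=9).coef_map
    shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
    b = fit_bodyfat_model(shuffled, "ml", seed=9).coef_map
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_bodyfat_constant_shift_moves_only_intercept():
    data = _demo_frame(seed=8)
    base = fit_bodyfat_model(data, "ml", seed=2, prior_sd=None).coef_map
    shifted = data.copy()
    shifted["tradeoff_ml"] = shifted["tradeoff_ml"] + 5.0
    out = fit_bodyfat_model(shifted, "ml", seed=2, prior_sd=None).coef_map
    # intercept absorbs -5*beta_pred; slopes unchanged (flat-prior limit)
    assert out[0] == pytest.approx(base[0] - 5.0 * base[1], rel=1e-8)
    assert out[1] == pytest.approx(base[1], rel=1e-8)


def test_constant_lactation_reduces_model():
    data = _demo_frame(seed=10)
    data["lact"] = 1
    with pytest.warns(UserWarning, match="constant"):
        post = fit_bodyfat_model(data, "ml", seed=1)
    assert post.terms == ("intercept", "pred")


def test_pregnancy_requires_both_outcomes():
    data = _demo_frame(seed=12)
    data["preg"] = 1
    with pytest.raises(ValueError):
        fit_pregnancy_model(data, "ml")


def test_separation_detected():
    data = _demo_frame(n=20, seed=14)
    data["preg"] = (data["tradeoff_ml"] > 0).astype(int)
    with pytest.warns(UserWarning, match="separation"):
        fit_pregnancy_model(data, "ml", seed=1)


def test_bodyfat_small_sample_rejected():
    with pytest.raises(ValueError):
        fit_bodyfat_model(_demo_frame(n=5), "ml")


def test_lactation_effect_recovery():
    """Simulated beta_lact = -2.89 is recovered nearly unbiasedly."""
    means = []
    for rep in range(50):
        demo = simulate_demography(
            np.random.default_rng(rep).standard_normal(27),
            beta_lact=-2.89, seed=1000 + rep,
        )
        post = fit_bodyfat_model(demo, "ml", seed=rep, draws=400)
        means.append(post.draws[:, list(post.terms).index("lact")].mean())
    assert abs(np.mean(means) - (-2.89)) < 0.4
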