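"""Per-individual forage–risk trade-off metrics and nonconsumptive-effect models.

The trade-off metric for a predator contrasts an individual's relative
probability of use of high-quality forage (the 95th percentile of
digestible energy across the third-order dataset) between high predator
risk (95th percentile) and low risk (5th percentile):

    delta_i = w_i(DE=q95, risk=q95) - w_i(DE=q95, risk=q05)

Negative values mean relative use of good forage is lower where risk is
high — a trade-off; positive values indicate risk-tolerant use.  The
other predator's covariate is held at its standardized mean (0) and the
intercept is excluded by default: it multiplies both terms of a metric
that is only defined up to relative scale.

The downstream nonconsumptive-effect (NCE) models regress fall body
condition and pregnancy on the trade-off metric, lactation status and
their interaction:

    IFBF_i       = a + b_pred*D_i + b_lact*L_i + b_pred:lact*D_i*L_i + e_i
    logit PREG_i = a + b_pred*D_i + b_lact*L_i + b_pred:lact*D_i*L_i

with Normal(0, 100) priors on the body-fat coefficients and intercepts
and Normal(0, 2) on the pregnancy slopes (scales are SDs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import RSFPosterior, fit_weighted_logistic, posterior_summary

__all__ = [
    "tradeoff_quantiles",
    "compute_tradeoff",
    "NCEPosterior",
    "fit_bodyfat_model",
    "fit_pregnancy_model",
    "SeparationWarning",
]


class SeparationWarning(UserWarning):
    pass


def tradeoff_quantiles(table: pd.DataFrame, de_q: float = 0.95,
                       hi_q: float = 0.95, lo_q: float = 0.05) -> dict:
    """Covariate quantiles "across the dataset" on the standardized scale."""
    return {
        "de": float(table["de"].quantile(de_q)),
        "ml_hi": float(table["ml"].quantile(hi_q)),
        "ml_lo": float(table["ml"].quantile(lo_q)),
        "wf_hi": float(table["wf"].quantile(hi_q)),
        "wf_lo": float(table["wf"].quantile(lo_q)),
    }


def _relative_use(coefs: pd.Series, de: float, risk: float, predator: str,
                  include_intercept: bool) -> float:
    lp = coefs["de"] * de + coefs[predator] * risk + coefs[f"de:{predator}"] * de * risk
    if include_intercept:
        lp += coefs["intercept"]
    return float(np.exp(lp))


def compute_tradeoff(
    post: RSFPosterior,
    table: pd.DataFrame,
    predator: str = "ml",
    de_q: float = 0.95,
    hi_q: float = 0.95,
    lo_q: float = 0.05,
    include_intercept: bool = False,
) -> pd.Series:
    """Per-individual trade-off metric from posterior-mean coefficients.

    The quantiles are computed from the (third-order) table's standardized
    covariate columns; the other predator sits at its mean (0), so its
    terms cancel from the difference exactly.
    """
    if predator not in ("ml", "wf"):
        raise ValueError("predator must be 'ml' or 'wf'")
    q = tradeoff_quantiles(table, de_q, hi_q, lo_q)
    de = q["de"]
    hi, lo = q[f"{predator}_hi"], q[f"{predator}_lo"]
    coefs = post.individual_coefficients()
    out = {}
    for ind in coefs.index:
        c = coefs.loc[ind]
        out[ind] = _relative_use(c, de, hi, predator, include_intercept) - _relative_use(
            c, de, lo, predator, include_intercept
        )
    return pd.Series(out, name=f"tradeoff_{predator}")


# ---------------------------------------------------------------------------
# NCE models
# ---------------------------------------------------------------------------

NCE_TERMS = ("intercept", "pred", "lact", "pred:lact")


@dataclass
class NCEPosterior:
    """Posterior draws for a nonconsumptive-effect regression."""

    terms: tuple[str, ...]
    draws: np.ndarray  # (M, p) coefficient draws
    coef_map: np.ndarray
    sigma_draws: np.ndarray | None = None  # residual SD (body-fat model)
    model: str = "bodyfat"
    seed: int | None = None

    def summary(self, level: float = 0.90) -> pd.DataFrame:
        rows = {}
        for i, t in enumerate(self.terms):
            mean, lo, hi = posterior_summary(self.draws[:, i], level)
            rows[f"beta_{t}"] = {"mean": mean, f"lo{int(level*100)}": lo,
                                 f"hi{int(level*100)}": hi}
        if self.sigma_draws is not None:
            mean, lo, hi = posterior_summary(self.sigma_draws, level)
            rows["sigma"] = {"mean": mean, f"lo{int(level*100)}": lo,
                             f"hi{int(level*100)}": hi}
        return pd.DataFrame(rows).T

    def to_dict(self, level: float = 0.90) -> dict:
        df = self.summary(level)
        return {k: {c: float(v) for c, v in row.items()} for k, row in df.iterrows()}


def _nce_design(data: pd.DataFrame, predator: str) -> tuple[np.ndarray, tuple[str, ...]]:
    pred = data[f"tradeoff_{predator}"].to_numpy(float)
    if not np.isfinite(pred).all():
        raise ValueError("trade-off covariate must be finite")
    lact = data["lact"].to_numpy(float)
    if np.ptp(lact) == 0:
        warnings.warn("lactation status is constant; fitting reduced model "
                      "without lactation terms")
        X = np.column_stack([np.ones(len(data)), pred])
        return X, ("intercept", "pred")
    X = np.column_stack([np.ones(len(data)), pred, lact, pred * lact])
    return X, NCE_TERMS


def fit_bodyfat_model(
    data: pd.DataFrame,
    predator: str = "ml",
    seed: int | None = None,
    draws: int = 2000,
    prior_sd: float | None = 100.0,
) -> NCEPosterior:
    """Gaussian-likelihood Bayesian regression of % ingesta-free body fat.

    Coefficients get Normal(0, 100) priors; the residual SD gets a flat
    prior on log(sigma).  Draws come from the conditional-conjugate
    normal/scaled-inverse-chi-square factorisation given the MAP
    precision (exact when the prior is flat).
    """
    if len(data) < 10:
        raise ValueError("need at least 10 animals for the body-fat model")
    X, terms = _nce_design(data, predator)
    y = data["ifbf"].to_numpy(float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    prec = 0.0 if prior_sd is None else 1.0 / prior_sd**2
    XtX = X.T @ X
    A = XtX + prec * np.eye(p)
    coef_map = np.linalg.solve(A, X.T @ y)
    resid = y - X @ coef_map
    # sigma^2 | y ~ scaled-inv-chi2; coef | sigma, y ~ Normal(coef_map, sigma^2 A^-1)
    df_sig = max(n - p, 1)
    s2 = float(resid @ resid) / df_sig
    sig2_draws = df_sig * s2 / rng.chisquare(df_sig, size=draws)
    Ainv = np.linalg.inv(A)
    L = np.linalg.cholesky((Ainv + Ainv.T) / 2)
    z = rng.standard_normal((draws, p))
    coef_draws = coef_map + np.sqrt(sig2_draws)[:, None] * (z @ L.T)
    return NCEPosterior(terms=terms, draws=coef_draws, coef_map=coef_map,
                        sigma_draws=np.sqrt(sig2_draws), model=f"bodyfat_{predator}",
                        seed=seed)


def fit_pregnancy_model(
    data: pd.DataFrame,
    predator: str = "ml",
    seed: int | None = None,
    draws: int = 2000,
    slope_prior_sd: float | None = 2.0,
    intercept_prior_sd: float | None = 100.0,
) -> NCEPosterior:
    """Bernoulli-logit Bayesian regression of pregnancy status.

    Laplace posterior around the penalized MAP.  Complete separation is
    detected (fitted probabilities all but degenerate) and reported; the
    priors still regularize the fit.
    """
    y = data["preg"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both pregnancy outcomes must be present")
    X, terms = _nce_design(data, predator)
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    if slope_prior_sd is None:
        prior = None
    else:
        prior = np.full(p, slope_prior_sd)
        prior[0] = intercept_prior_sd if intercept_prior_sd is not None else slope_prior_sd
    coef_map, H = fit_weighted_logistic(X, y, prior_sd=prior)
    fitted = expit(X @ coef_map)
    # perfect in-sample classification: the unpenalized MLE would diverge
    if np.all(fitted[y == 1] > 0.5) and np.all(fitted[y == 0] < 0.5):
        warnings.warn("complete separation detected in pregnancy model",
                      SeparationWarning)
    cov = np.linalg.inv(H)
    L = np.linalg.cholesky((cov + cov.T) / 2)
    coef_draws = coef_map + rng.standard_normal((draws, p)) @ L.T
    return NCEPosterior(terms=terms, draws=coef_draws, coef_map=coef_map,
                        model=f"pregnancy_{predator}", seed=seed)
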