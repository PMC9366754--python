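"""Weighted hierarchical Bayesian resource selection functions.

The RSF uses the exponential form w(x) = exp(eta), estimated as a weighted
used–available logistic regression (available rows weighted 1000) with a
random intercept and random slopes/interactions per individual, centred
hierarchically on the population coefficients:

    eta_ij = g0_i + gDE_i*DE_j + gML_i*ML_j + gWF_i*WF_j
             + gDExML_i*DE_j*ML_j + gDExWF_i*DE_j*WF_j
    g0_i   ~ Normal(b0, 100)          (scale fixed, not estimated)
    gcov_i ~ Normal(bcov, sigma_cov),  sigma_cov ~ Uniform(0, 2)
    bcov   ~ Normal(0, 2)

All prior scale parameters are standard deviations.  Estimation uses a
Laplace-marginalised likelihood: for candidate population parameters the
per-individual coefficients are profiled out by an inner Newton solve and
a Laplace correction (the same construction as glmmTMB), the outer
posterior is maximised numerically, and draws come either from a Gaussian
(Laplace) approximation at the mode or from an ensemble MCMC run over the
marginal posterior.  Per-individual coefficients are then drawn from
their conditional Laplace approximation given each population draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = [
    "TERMS",
    "RSFModelSpec",
    "RSFPosterior",
    "ConvergenceWarning",
    "design_matrix",
    "fit_weighted_logistic",
    "fit_hierarchical_rsf",
    "predict_relative_use",
    "posterior_summary",
]

TERMS = ("intercept", "de", "ml", "wf", "de:ml", "de:wf")


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class RSFModelSpec:
    """Structure and priors of the hierarchical RSF.

    ``fixed_prior_scale`` is the SD of the Normal(0, .) prior on population
    coefficients (None = flat).  ``intercept_ranef_scale`` is the FIXED SD
    of the random intercepts — deliberately wide (100) so individual
    intercepts absorb unbalanced sampling without shrinking to the mean.
    ``slope_sd_upper`` bounds the Uniform(0, .) prior on random-slope SDs.
    """

    terms: tuple[str, ...] = TERMS
    random_slopes: bool = True
    fixed_prior_scale: float | None = 2.0
    intercept_ranef_scale: float = 100.0
    slope_sd_upper: float = 2.0

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def slope_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if t != "intercept")


def design_matrix(table: pd.DataFrame, terms=TERMS) -> np.ndarray:
    """Model matrix from standardized covariate columns de/ml/wf."""
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(len(table)))
        elif ":" in t:
            a, b = t.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[t].to_numpy(float))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariates in design matrix")
    return X


# ---------------------------------------------------------------------------
# Weighted logistic building block (also the oracle-comparable MAP)
# ---------------------------------------------------------------------------

def _weighted_logistic_obj(coef, X, y, w, prior_prec, prior_mean):
    eta = X @ coef
    ll = np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
    if prior_prec is not None:
        ll -= 0.5 * np.sum(prior_prec * (coef - prior_mean) ** 2)
    return ll


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    prior_sd: np.ndarray | float | None = None,
    prior_mean: np.ndarray | float = 0.0,
    coef0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped-Newton MAP for a weighted Bernoulli-logit model.

    With ``prior_sd=None`` this is the weighted maximum-likelihood
    (IRLS) estimate.  Returns the coefficient vector and the negative
    Hessian of the log posterior at the mode (the Laplace precision).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    w = np.ones(n) if w is None else np.asarray(w, float)
    if prior_sd is None:
        prec = None
        pm = np.zeros(p)
    else:
        sd = np.broadcast_to(np.asarray(prior_sd, float), (p,)).copy()
        prec = 1.0 / sd**2
        pm = np.broadcast_to(np.asarray(prior_mean, float), (p,)).copy()
    coef = np.zeros(p) if coef0 is None else np.asarray(coef0, float).copy()
    obj = _weighted_logistic_obj(coef, X, y, w, prec, pm)
    H = None
    for _ in range(max_iter):
        eta = X @ coef
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        wt = w * mu * (1 - mu)
        H = X.T @ (X * wt[:, None])
        if prec is not None:
            grad -= prec * (coef - pm)
            H = H + np.diag(prec)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # backtracking keeps the iteration inside the concave region
        t = 1.0
        for _ in range(30):
            new = coef + t * step
            new_obj = _weighted_logistic_obj(new, X, y, w, prec, pm)
            if new_obj >= obj - 1e-12:
                break
            t *= 0.5
        coef, gain, obj = new, new_obj - obj, new_obj
        if np.max(np.abs(grad)) < tol or abs(gain) < tol:
            break
    else:
        warnings.warn("weighted logistic Newton did not converge", ConvergenceWarning)
    return coef, H


# ---------------------------------------------------------------------------
# Hierarchical model internals
# ---------------------------------------------------------------------------

class _Groups:
    """Per-individual data padded to a common length (pad rows have weight 0)."""

    def __init__(self, table: pd.DataFrame, terms):
        ids = table["individual_id"].astype(str).to_numpy()
        self.individuals = sorted(set(ids))
        X = design_matrix(table, terms)
        y = table["used"].to_numpy(float)
        w = table["weight"].to_numpy(float)
        counts = [np.sum(ids == g) for g in self.individuals]
        nmax, G, p = max(counts), len(self.individuals), X.shape[1]
        self.X = np.zeros((G, nmax, p))
        self.y = np.zeros((G, nmax))
        self.w = np.zeros((G, nmax))
        for k, g in enumerate(self.individuals):
            m = ids == g
            c = counts[k]
            self.X[k, :c] = X[m]
            self.y[k, :c] = y[m]
            self.w[k, :c] = w[m]
        self.XT = np.ascontiguousarray(self.X.transpose(0, 2, 1))
        self.G, self.p = G, p


def _inner_newton(groups: _Groups, beta, d, gamma0, tol=1e-8, max_iter=50):
    """Batched per-individual penalized-logistic modes given (beta, d).

    Returns (gamma, H) where H is the (G, p, p) negative Hessian of the
    joint log density in gamma at the mode.
    """
    X, y, w = groups.X, groups.y, groups.w
    XT = groups.XT
    prec = 1.0 / d**2  # (p,)
    gamma = gamma0.copy()

    def obj(g):
        eta = (X @ g[:, :, None])[..., 0]
        ll = np.sum(w * (y * eta - np.logaddexp(0.0, eta)), axis=1)
        return ll - 0.5 * np.sum(prec * (g - beta) ** 2, axis=1)

    cur = obj(gamma)
    H = None
    for _ in range(max_iter):
        eta = (X @ gamma[:, :, None])[..., 0]
        mu = expit(eta)
        grad = (XT @ (w * (y - mu))[:, :, None])[..., 0] - prec * (gamma - beta)
        wt = w * mu * (1 - mu)
        H = XT @ (X * wt[:, :, None])
        H = H + np.diag(prec)[None, :, :]
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        if np.max(np.abs(step)) < 0.5:
            # small Newton steps on a strictly concave objective are safe;
            # skip the objective evaluation of the backtracking safeguard
            gamma = gamma + step
        else:
            t = np.ones(groups.G)
            for _ in range(30):
                new = gamma + t[:, None] * step
                new_obj = obj(new)
                bad = new_obj < cur - 1e-12
                if not bad.any():
                    break
                t[bad] *= 0.5
            gamma, cur = new, np.maximum(new_obj, cur)
        if np.max(np.abs(grad)) < tol:
            break
    return gamma, H


def _log_marginal(groups: _Groups, beta, d, gamma_cache):
    """Laplace-marginalised log likelihood summed over individuals.

    marginal_g = joint(gamma*_g) - sum(log d) - 0.5*logdet(H_g); the
    (p/2)log(2pi) factors of prior normalisation and Laplace integral
    cancel exactly.
    """
    gamma, H = _inner_newton(groups, beta, d, gamma_cache["gamma"])
    gamma_cache["gamma"] = gamma
    X, y, w = groups.X, groups.y, groups.w
    eta = (X @ gamma[:, :, None])[..., 0]
    ll = np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
    pen = -0.5 * np.sum(((gamma - beta) / d) ** 2)
    sign, logdet = np.linalg.slogdet(H)
    if np.any(sign <= 0):
        return -np.inf, gamma, H
    total = ll + pen - groups.G * np.sum(np.log(d)) - 0.5 * np.sum(logdet)
    return total, gamma, H


@dataclass
class RSFPosterior:
    """Posterior draws and summaries for the hierarchical RSF."""

    terms: tuple[str, ...]
    slope_terms: tuple[str, ...]
    individuals: list[str]
    beta_draws: np.ndarray  # (M, p)
    sigma_draws: np.ndarray  # (M, n_slopes)
    gamma_draws: np.ndarray  # (M, G, p)
    beta_map: np.ndarray
    sigma_map: np.ndarray
    gamma_map: np.ndarray
    method: str = "laplace"
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    def parameter_draws(self) -> dict[str, np.ndarray]:
        out = {f"beta_{t}": self.beta_draws[:, i] for i, t in enumerate(self.terms)}
        out.update(
            {f"sigma_{t}": self.sigma_draws[:, i] for i, t in enumerate(self.slope_terms)}
        )
        return out

    def summary(self, level: float = 0.90) -> pd.DataFrame:
        rows = {}
        if self.n_draws == 0:  # MAP-only fit: point estimates, no intervals
            maps = {f"beta_{t}": self.beta_map[i] for i, t in enumerate(self.terms)}
            maps.update(
                {f"sigma_{t}": self.sigma_map[i] for i, t in enumerate(self.slope_terms)}
            )
            for name, v in maps.items():
                rows[name] = {
                    "mean": float(v),
                    f"lo{int(level*100)}": np.nan, f"hi{int(level*100)}": np.nan,
                    "rhat": np.nan, "ess": np.nan,
                }
            return pd.DataFrame(rows).T
        for name, draws in self.parameter_draws().items():
            mean, lo, hi = posterior_summary(draws, level)
            diag = self.diagnostics.get(name, {})
            rows[name] = {
                "mean": mean,
                f"lo{int(level*100)}": lo,
                f"hi{int(level*100)}": hi,
                "rhat": diag.get("rhat", np.nan),
                "ess": diag.get("ess", np.nan),
            }
        return pd.DataFrame(rows).T

    def individual_coefficients(self, stat: str = "mean") -> pd.DataFrame:
        """Per-individual coefficient posterior means (rows: individuals)."""
        if self.n_draws == 0:
            vals = self.gamma_map
        elif stat == "mean":
            vals = self.gamma_draws.mean(axis=0)
        elif stat == "median":
            vals = np.median(self.gamma_draws, axis=0)
        else:
            raise ValueError(f"unknown stat {stat!r}")
        return pd.DataFrame(vals, index=self.individuals, columns=list(self.terms))


def posterior_summary(draws, level: float = 0.90) -> tuple[float, float, float]:
    """Mean and equal-tailed credible interval of a draw vector."""
    draws = np.asarray(draws, float).ravel()
    if draws.size == 0:
        raise ValueError("empty draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(draws.mean()), float(lo), float(hi)


def _diagnostics(draws: dict[str, np.ndarray], n_chains: int = 4) -> dict:
    import arviz as az

    out = {}
    for name, x in draws.items():
        m = (len(x) // n_chains) * n_chains
        if m < n_chains * 2:
            out[name] = {"rhat": np.nan, "ess": np.nan}
            continue
        arr = x[:m].reshape(n_chains, -1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = {"rhat": float(az.rhat(arr)), "ess": float(az.ess(arr))}
    return out


def _theta_unpack(theta, p, n_s, upper):
    beta = theta[:p]
    s = theta[p:]
    sigma = upper * expit(s)
    return beta, s, sigma


def fit_hierarchical_rsf(
    table: pd.DataFrame,
    spec: RSFModelSpec | None = None,
    method: str = "laplace",
    draws: int = 400,
    seed: int | None = None,
    mcmc_walkers: int = 32,
    mcmc_warmup: int = 400,
    mcmc_steps: int = 400,
    rhat_threshold: float = 1.05,
) -> RSFPosterior:
    """Fit the weighted hierarchical RSF on a standardized used–available table.

    ``method`` is ``"laplace"`` (marginal mode + Gaussian draws, default),
    ``"map"`` (mode only, no draws — the fast cross-validation mode) or
    ``"mcmc"`` (ensemble MCMC over the marginal posterior).  Per-row
    log-likelihood contributions are multiplied by the ``weight`` column.
    """
    spec = spec or RSFModelSpec()
    if table["individual_id"].nunique() < 2 and spec.random_slopes:
        raise ValueError("hierarchical fit needs at least 2 individuals")
    rng = np.random.default_rng(seed)

    if not spec.random_slopes:
        return _fit_fixed_effects(table, spec, draws, rng, seed, method)

    groups = _Groups(table, spec.terms)
    p = groups.p
    n_s = len(spec.slope_terms)
    upper = spec.slope_sd_upper

    def dvec(sigma):
        d = np.empty(p)
        j = 0
        for i, t in enumerate(spec.terms):
            if t == "intercept":
                d[i] = spec.intercept_ranef_scale
            else:
                d[i] = sigma[j]
                j += 1
        return d

    cache = {"gamma": np.zeros((groups.G, p))}
    # initialise beta at the pooled fixed-effects MAP
    Xall = design_matrix(table, spec.terms)
    beta0, _ = fit_weighted_logistic(
        Xall, table["used"].to_numpy(float), table["weight"].to_numpy(float),
        prior_sd=spec.fixed_prior_scale,
    )
    cache["gamma"][:] = beta0

    prior_prec_beta = (
        None if spec.fixed_prior_scale is None else 1.0 / spec.fixed_prior_scale**2
    )

    def neg_log_post(theta):
        beta, s, sigma = _theta_unpack(theta, p, n_s, upper)
        if np.any(sigma <= 1e-8):
            return np.inf
        lm, _, _ = _log_marginal(groups, beta, dvec(sigma), cache)
        if not np.isfinite(lm):
            return np.inf
        lp = lm
        if prior_prec_beta is not None:
            lp -= 0.5 * prior_prec_beta * np.sum(beta**2)
        # Uniform(0, upper) prior on sigma is flat; add the s -> sigma Jacobian
        sig01 = expit(s)
        lp += np.sum(np.log(upper) + np.log(sig01) + np.log1p(-sig01))
        return -lp

    s0 = np.full(n_s, np.log(0.3 / (upper - 0.3)))  # sigma ~ 0.3 start
    theta0 = np.concatenate([beta0, s0])
    res = optimize.minimize(
        neg_log_post, theta0, method="L-BFGS-B",
        options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success and "MAXLINE" not in str(res.message).upper():
        warnings.warn(f"outer optimisation: {res.message}", ConvergenceWarning)
    theta_hat = res.x
    beta_hat, s_hat, sigma_hat = _theta_unpack(theta_hat, p, n_s, upper)
    gamma_hat, H_hat = _inner_newton(groups, beta_hat, dvec(sigma_hat), cache["gamma"])

    if method == "map" or draws == 0:
        post = RSFPosterior(
            terms=spec.terms, slope_terms=spec.slope_terms,
            individuals=groups.individuals,
            beta_draws=np.empty((0, p)), sigma_draws=np.empty((0, n_s)),
            gamma_draws=np.empty((0, groups.G, p)),
            beta_map=beta_hat, sigma_map=sigma_hat, gamma_map=gamma_hat,
            method="map", seed=seed,
        )
        return post

    if method == "laplace":
        theta_draws = _laplace_theta_draws(neg_log_post, theta_hat, draws, rng)
    elif method == "mcmc":
        theta_draws = _ensemble_theta_draws(
            neg_log_post, theta_hat, draws, rng,
            n_walkers=max(mcmc_walkers, 2 * len(theta_hat) + 2),
            warmup=mcmc_warmup, steps=mcmc_steps,
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    M = theta_draws.shape[0]
    beta_draws = theta_draws[:, :p]
    sigma_draws = upper * expit(theta_draws[:, p:])
    gamma_draws = np.empty((M, groups.G, p))
    g_warm = gamma_hat.copy()
    for m in range(M):
        d = dvec(sigma_draws[m])
        g_mode, H = _inner_newton(groups, beta_draws[m], d, g_warm, tol=1e-6, max_iter=25)
        g_warm = g_mode
        L = np.linalg.cholesky(np.linalg.inv(H))
        z = rng.standard_normal((groups.G, p))
        gamma_draws[m] = g_mode + np.einsum("gpq,gq->gp", L, z)

    post = RSFPosterior(
        terms=spec.terms, slope_terms=spec.slope_terms,
        individuals=groups.individuals,
        beta_draws=beta_draws, sigma_draws=sigma_draws, gamma_draws=gamma_draws,
        beta_map=beta_hat, sigma_map=sigma_hat, gamma_map=gamma_hat,
        method=method, seed=seed,
    )
    post.diagnostics = _diagnostics(post.parameter_draws())
    bad = [k for k, v in post.diagnostics.items()
           if np.isfinite(v["rhat"]) and v["rhat"] > rhat_threshold]
    if bad:
        warnings.warn(
            f"potential scale reduction above {rhat_threshold} for: {bad}",
            ConvergenceWarning,
        )
    return post


def _laplace_theta_draws(neg_log_post, theta_hat, draws, rng):
    """Gaussian draws from the Laplace approximation at the marginal mode."""
    k = len(theta_hat)
    h = 1e-4 * np.maximum(np.abs(theta_hat), 1.0)
    H = np.empty((k, k))
    f0 = neg_log_post(theta_hat)
    # central second differences (objective is smooth in theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                fpp = neg_log_post(theta_hat + ei)
                fmm = neg_log_post(theta_hat - ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
            else:
                fpp = neg_log_post(theta_hat + ei + ej)
                fpm = neg_log_post(theta_hat + ei - ej)
                fmp = neg_log_post(theta_hat - ei + ej)
                fmm = neg_log_post(theta_hat - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    # guard against numerical non-PD curvature
    vals, vecs = np.linalg.eigh((H + H.T) / 2)
    vals = np.maximum(vals, 1e-8)
    cov = (vecs / vals) @ vecs.T
    L = np.linalg.cholesky((cov + cov.T) / 2)
    return theta_hat + rng.standard_normal((draws, k)) @ L.T


def _ensemble_theta_draws(neg_log_post, theta_hat, draws, rng, n_walkers, warmup, steps):
    import emcee

    k = len(theta_hat)

    def log_prob(theta):
        v = neg_log_post(theta)
        return -v if np.isfinite(v) else -np.inf

    p0 = theta_hat + 1e-3 * rng.standard_normal((n_walkers, k))
    sampler = emcee.EnsembleSampler(n_walkers, k, log_prob)
    state = sampler.run_mcmc(p0, warmup, progress=False,
                             rstate0=np.random.RandomState(rng.integers(2**31 - 1)))
    sampler.reset()
    sampler.run_mcmc(state, steps, progress=False)
    chain = sampler.get_chain(flat=True)
    idx = rng.choice(len(chain), size=min(draws, len(chain)), replace=False)
    return chain[idx]


def _fit_fixed_effects(table, spec, draws, rng, seed, method):
    """Fixed-effects-only weighted logistic (no random structure)."""
    X = design_matrix(table, spec.terms)
    y = table["used"].to_numpy(float)
    w = table["weight"].to_numpy(float)
    coef, H = fit_weighted_logistic(X, y, w, prior_sd=spec.fixed_prior_scale)
    p = len(coef)
    if draws > 0 and method != "map":
        cov = np.linalg.inv(H)
        L = np.linalg.cholesky((cov + cov.T) / 2)
        beta_draws = coef + rng.standard_normal((draws, p)) @ L.T
    else:
        beta_draws = np.empty((0, p))
    ids = sorted(table["individual_id"].astype(str).unique())
    G = len(ids)
    gamma_draws = np.repeat(beta_draws[:, None, :], G, axis=1) if len(beta_draws) else np.empty((0, G, p))
    post = RSFPosterior(
        terms=spec.terms, slope_terms=(), individuals=ids,
        beta_draws=beta_draws, sigma_draws=np.empty((len(beta_draws), 0)),
        gamma_draws=gamma_draws,
        beta_map=coef, sigma_map=np.empty(0),
        gamma_map=np.tile(coef, (G, 1)),
        method=method if method else "laplace", seed=seed,
    )
    if len(beta_draws):
        post.diagnostics = _diagnostics(post.parameter_draws())
    return post


def predict_relative_use(
    post: RSFPosterior,
    covariates: pd.DataFrame,
    level: str = "population",
    individual: str | None = None,
    include_intercept: bool = True,
) -> np.ndarray:
    """Relative use w = exp(linear predictor) at standardized covariates.

    ``level="population"`` uses the population coefficients' posterior
    means; ``level="individual"`` uses the named individual's coefficient
    means.
    """
    X = design_matrix(covariates, post.terms)
    if level == "population":
        coef = post.beta_draws.mean(axis=0) if post.n_draws else post.beta_map
    elif level == "individual":
        if individual is None or str(individual) not in post.individuals:
            raise KeyError(f"unknown individual {individual!r}")
        g = post.individual_coefficients()
        coef = g.loc[str(individual)].to_numpy()
    else:
        raise ValueError(f"unknown level {level!r}")
    if not include_intercept:
        coef = coef.copy()
        coef[list(post.terms).index("intercept")] = 0.0
    return np.exp(X @ coef)
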