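"""Step-size distribution fitting and WAIC model comparison.

Six candidate models for the pooled step sizes (meters per 10 s fix
interval): folded normal, log-normal and Pareto, each in a plain and an
upper-truncated form. The truncated form renormalises the density to an
estimated upper bound tau,

    f_trunc(x) = f(x) / F(tau),   0 < x <= tau,

with tau a free parameter bounded below by the largest observed step
(uniform prior on [max r, 2 max r]). Because tau's likelihood piles up
against that lower bound, these models are sampled with the
affine-invariant ensemble MCMC of emcee rather than a Gaussian
approximation.

Models are compared by the Watanabe-Akaike information criterion on the
deviance scale,

    WAIC = -2 * (lppd - p_waic),
    lppd = sum_i log mean_d exp(ll[d, i]),
    p_waic = sum_i var_d(ll[d, i]),

computed from the matrix of pointwise log-likelihoods over posterior
draws d and observations i; lower is better. Akaike weights are
proportional to exp(-dWAIC / 2).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import emcee
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp

from ._inference import SamplerConfig

FAMILIES = ("folded_normal", "lognormal", "pareto")


@dataclass
class DistModelFit:
    """Posterior fit of one step-size distribution family."""

    family: str
    truncated: bool
    param_names: list[str]
    draws: np.ndarray              # (n_draws, p) on the natural scale
    loglik: np.ndarray             # (n_draws, n_obs) pointwise
    n_obs: int
    diagnostics: dict

    @property
    def label(self) -> str:
        return ("truncated " if self.truncated else "") + self.family

    def summary(self) -> pd.DataFrame:
        q = np.percentile(self.draws, [2.5, 5.0, 50.0, 95.0, 97.5], axis=0)
        return pd.DataFrame(
            {"median": q[2], "ci2.5": q[0], "ci5": q[1],
             "ci95": q[3], "ci97.5": q[4]},
            index=pd.Index(self.param_names, name="param"))

    def waic(self):
        return waic(self.loglik)


def _family_logpdf(family: str, x, log_x, theta):
    """Pointwise log-density and log-CDF-at-tau machinery per family."""
    if family == "folded_normal":
        mu, sigma = theta[0], theta[1]
        return np.logaddexp(stats.norm.logpdf(x, mu, sigma),
                            stats.norm.logpdf(x, -mu, sigma))
    if family == "lognormal":
        mu, sigma = theta[0], theta[1]
        return stats.norm.logpdf(log_x, mu, sigma) - log_x
    # pareto: theta = (alpha, xmin)
    alpha, xmin = theta[0], theta[1]
    return np.log(alpha) + alpha * np.log(xmin) - (alpha + 1) * log_x


def _family_logcdf(family: str, tau, theta):
    if family == "folded_normal":
        mu, sigma = theta[0], theta[1]
        val = (stats.norm.cdf(tau, mu, sigma) - stats.norm.cdf(-tau, mu, sigma))
        return np.log(max(val, 1e-300))
    if family == "lognormal":
        mu, sigma = theta[0], theta[1]
        return stats.norm.logcdf(np.log(tau), mu, sigma)
    alpha, xmin = theta[0], theta[1]
    with np.errstate(divide="ignore"):
        return np.log1p(-((xmin / tau) ** alpha))


def _unpack(family: str, truncated: bool, par, xmin, rmax):
    """Unconstrained sampling vector -> natural parameters (+ log-Jacobian)."""
    if family == "pareto":
        alpha = np.exp(par[0])
        theta = (alpha, xmin)
        logjac = par[0]
        lp = stats.expon.logpdf(alpha, scale=1.0)      # shape ~ Exponential(1)
    else:
        mu, sigma = par[0], np.exp(par[1])
        theta = (mu, sigma)
        logjac = par[1]
        lp = stats.norm.logpdf(mu, 0, 5) + stats.expon.logpdf(sigma, scale=1.0)
    tau = None
    if truncated:
        u = expit(par[-1])
        tau = rmax * (1.0 + u)                          # uniform on [rmax, 2 rmax]
        logjac += np.log(u) + np.log1p(-u)              # d tau / d par, up to rmax
    return theta, tau, lp + logjac


def fit_step_distribution(r_values, family: str, truncated: bool = False,
                          sampler_cfg: SamplerConfig | None = None,
                          seed: int = 0) -> DistModelFit:
    """Bayesian fit of one of the six candidate step-size models.

    ``r_values`` are positive step sizes (floor small steps first; see
    :func:`ars_search.kinematics.floor_steps`). The Pareto lower bound
    is fixed at the smallest observation.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    r = np.asarray(r_values, dtype=float)
    if np.any(r <= 0):
        raise ValueError("step sizes must be strictly positive")
    if r.size < 100:
        warnings.warn(f"only {r.size} step sizes; fits may be unstable",
                      stacklevel=2)
    cfg = sampler_cfg or SamplerConfig(chains=4, draws=250, warmup=300)
    log_r = np.log(r)
    xmin, rmax = float(r.min()), float(r.max())
    n = r.size

    def log_prob(par):
        theta, tau, lp = _unpack(family, truncated, par, xmin, rmax)
        if not np.isfinite(lp):
            return -np.inf
        ll = _family_logpdf(family, r, log_r, theta)
        if truncated:
            ll = ll - _family_logcdf(family, tau, theta)
        total = np.sum(ll)
        return lp + total if np.isfinite(total) else -np.inf

    ndim = (1 if family == "pareto" else 2) + (1 if truncated else 0)
    nwalkers = max(2 * ndim + 2, 16)
    rng = np.random.default_rng(seed)
    if family == "pareto":
        alpha0 = 1.0 / max(np.mean(log_r - np.log(xmin)), 1e-3)
        center = [np.log(alpha0)]
    else:
        center = [np.mean(log_r) if family == "lognormal" else np.mean(r),
                  np.log(np.std(log_r) if family == "lognormal" else np.std(r))]
    if truncated:
        center.append(0.0)
    p0 = np.array(center) + 0.05 * rng.standard_normal((nwalkers, ndim))

    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
    sampler._random = np.random.RandomState(seed % 2**32)  # reproducible across processes
    state = sampler.run_mcmc(p0, cfg.warmup, progress=False,
                             skip_initial_state_check=True)
    sampler.reset()
    n_keep = int(np.ceil(cfg.total_draws / nwalkers))
    sampler.run_mcmc(state, n_keep * max(cfg.thin, 1), thin_by=max(cfg.thin, 1),
                     progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(flat=True)[: cfg.total_draws]

    # natural-scale draws + pointwise log-likelihood per retained draw
    names = (["alpha"] if family == "pareto" else ["mu", "sigma"])
    if truncated:
        names = names + ["tau"]
    nat = np.empty((chain.shape[0], len(names)))
    ll = np.empty((chain.shape[0], n))
    for d, par in enumerate(chain):
        theta, tau, _ = _unpack(family, truncated, par, xmin, rmax)
        row = _family_logpdf(family, r, log_r, theta)
        if truncated:
            row = row - _family_logcdf(family, tau, theta)
        ll[d] = row
        nat[d] = ([theta[0]] if family == "pareto" else [theta[0], theta[1]]) \
            + ([tau] if truncated else [])

    acc = float(np.mean(sampler.acceptance_fraction))
    diag = {"acceptance_fraction": acc, "method": "emcee",
            "n_draws": int(chain.shape[0]), "xmin": xmin, "rmax": rmax}
    if acc < 0.1:
        diag["warning"] = "low MCMC acceptance fraction"
    return DistModelFit(family=family, truncated=truncated, param_names=names,
                        draws=nat, loglik=ll, n_obs=n, diagnostics=diag)


def waic(pointwise_loglik: np.ndarray):
    """WAIC on the deviance scale from a draws x observations matrix.

    Returns ``(waic, se, p_waic)`` where ``se`` is the sampling standard
    error of the WAIC over observations.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2) x observations matrix")
    if not np.all(np.isfinite(ll)):
        bad = np.flatnonzero(~np.all(np.isfinite(ll), axis=0))
        raise ValueError(f"non-finite log-likelihoods at observations {bad.tolist()}")
    D, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(D)
    p_i = np.var(ll, axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    w = -2.0 * np.sum(elpd_i)
    se = 2.0 * np.sqrt(n * np.var(elpd_i, ddof=1)) if n > 1 else 0.0
    return float(w), float(se), float(np.sum(p_i))


def compare_models(fits: list[DistModelFit]) -> pd.DataFrame:
    """WAIC comparison table: sorted ascending, dWAIC and Akaike weights."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    sizes = {f.n_obs for f in fits}
    if len(sizes) > 1:
        raise ValueError(f"fits are on different data sizes: {sorted(sizes)}")
    rows = []
    for f in fits:
        w, se, p = waic(f.loglik)
        rows.append({"model": f.label, "waic": w, "se": se, "p_waic": p})
    df = pd.DataFrame(rows).sort_values("waic", ignore_index=True)
    df["d_waic"] = df["waic"] - df["waic"].iloc[0]
    raw = np.exp(-0.5 * df["d_waic"].to_numpy())
    df["weight"] = raw / raw.sum()
    return df


def fit_all_models(r_values, sampler_cfg: SamplerConfig | None = None,
                   seed: int = 0) -> list[DistModelFit]:
    """Fit all six candidate models on the same data."""
    fits = []
    for i, family in enumerate(FAMILIES):
        for j, truncated in enumerate((False, True)):
            fits.append(fit_step_distribution(
                r_values, family, truncated, sampler_cfg, seed=seed + 10 * i + j))
    return fits
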