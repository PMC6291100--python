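"""Lagged Bayesian models of turning angle and step size.

The central question is whether recent prey encounters change how a
forager moves. Both outcomes are modelled as functions of the encounter
history over the previous S time steps:

* turning angle, a unit-interval variable, follows a Beta regression

      delta[t] ~ Beta(mu[t] * nu, (1 - mu[t]) * nu)
      mu[t] = logit^-1(psi[0] + sum_s psi[s] * E[t - s])

  where E[t-s] indicates an encounter s steps before t. A uniform
  turning-angle distribution — the Levy-flight assumption — is the
  special case psi[0] = 0, psi[s] = 0, nu = 2.

* step size (meters per 10 s fix interval, a velocity proxy) follows

      r[t] ~ LogNormal(eta[t], omega)
      eta[t] = phi[0] + sum_s phi[s] * E[t - s]

Area-restricted search predicts psi[s] > 0 (more turning after an
encounter) and phi[s] < 0 (slower movement after an encounter), both
decaying with lag s.

Two robustness variants are provided: an AR-1 term (the link-scale value
of the previous outcome enters the predictor) to absorb temporal
autocorrelation, and a split of each lag curve by encounter type (prey
shot-and-hit vs not), since post-hit behaviour may reflect item recovery
rather than continued search.

Priors are weakly informative: Normal(0, 5) on intercepts, Normal(0, 1)
on lag coefficients and the AR-1 coefficient, Exponential(0.1) on the
positive dispersion parameters. Lag coefficients are a-priori
independent; an optional random-walk smoothing prior across lags can be
switched on via ``rw_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, logit

from ._inference import Posterior, SamplerConfig, laplace_sample
from .kinematics import PolarSeries, floor_steps, squeeze_unit


@dataclass
class Priors:
    intercept_sd: float = 5.0
    lag_sd: float = 1.0
    ar_sd: float = 1.0
    dispersion_rate: float = 0.1   # Exponential rate on nu / omega
    rw_scale: float | None = None  # random-walk smoothing across lags (off)


@dataclass
class LagDesign:
    """Outcome series with its per-trip encounter lag matrix.

    ``lags[t, s-1]`` is E[t-s]; entries referring to time before the
    start of a trip (or before a cadence gap) are zero, and rows with an
    undefined outcome are dropped. ``prev_link`` holds the link-scale
    value of the outcome one step earlier (NaN where unavailable) for the
    AR-1 variant; ``lags_hit``/``lags_nonhit`` split the lag matrix by
    encounter type for the split variant.
    """

    outcome: np.ndarray
    kind: str                     # 'delta' or 'r'
    S: int
    lags: np.ndarray
    lags_hit: np.ndarray
    lags_nonhit: np.ndarray
    prev_link: np.ndarray
    trip_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.outcome.size


def _lag_matrix(e: np.ndarray, S: int) -> np.ndarray:
    n = e.size
    L = np.zeros((n, S), dtype=np.float64)
    for s in range(1, S + 1):
        if s < n:
            L[s:, s - 1] = e[:-s]
    return L


def build_lag_design(series: PolarSeries | list[PolarSeries], S: int,
                     outcome: str = "delta") -> LagDesign:
    """Assemble the lagged-encounter design for one or more trips.

    Lags never cross trip boundaries or cadence gaps. For the turning
    angle outcome, steps without a defined turn are dropped and the
    remaining values are squeezed off the unit-interval endpoints; for
    step size, values are floored at the stationarity half-threshold
    before the log-normal likelihood.
    """
    if S < 1:
        raise ValueError("at least one lag required (S >= 1)")
    if outcome not in ("delta", "r"):
        raise ValueError(f"unknown outcome {outcome!r}")
    series_list = [series] if isinstance(series, PolarSeries) else list(series)

    ys, lag_blocks, hit_blocks, non_blocks, prevs, trips = [], [], [], [], [], []
    for ps in series_list:
        if S >= ps.n_steps:
            raise ValueError(
                f"lag depth S={S} must be smaller than trip length "
                f"{ps.n_steps} (trip {ps.trip_id!r})")
        for seg in np.unique(ps.segment):
            m = ps.segment == seg
            e = ps.E[m].astype(float)
            e_hit = ((ps.E[m] == 1) & (ps.E_kind[m] == "hit")).astype(float)
            L = _lag_matrix(e, S)
            L_hit = _lag_matrix(e_hit, S)
            L_non = L - L_hit

            if outcome == "delta":
                y_raw = ps.delta[m]
                keep = ps.valid_delta[m]
                prev = np.full(m.sum(), np.nan)
                prev[1:] = y_raw[:-1]          # link applied after squeeze
            else:
                y_raw = floor_steps(ps.r[m])
                keep = np.ones(m.sum(), dtype=bool)
                prev = np.full(m.sum(), np.nan)
                prev[1:] = np.log(y_raw[:-1])

            ys.append(y_raw[keep])
            lag_blocks.append(L[keep])
            hit_blocks.append(L_hit[keep])
            non_blocks.append(L_non[keep])
            prevs.append(prev[keep])
            trips.append(np.repeat(ps.trip_id, keep.sum()))

    y = np.concatenate(ys)
    prev = np.concatenate(prevs)
    if outcome == "delta":
        n = y.size
        y = squeeze_unit(y, n)
        with np.errstate(invalid="ignore"):
            prev = logit(squeeze_unit(prev, n))
    return LagDesign(
        outcome=y, kind=outcome, S=S,
        lags=np.vstack(lag_blocks),
        lags_hit=np.vstack(hit_blocks),
        lags_nonhit=np.vstack(non_blocks),
        prev_link=prev,
        trip_ids=np.concatenate(trips),
    )


@dataclass
class LagFit:
    """Posterior over a lagged effect curve and its dispersion."""

    model: str                 # 'beta' or 'lognormal'
    variant: str               # 'plain', 'ar1' or 'split'
    S: int
    posterior: Posterior
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.summary = self.posterior.summary()

    @property
    def diagnostics(self) -> dict:
        return self.posterior.diagnostics

    def lag_summary(self, kind: str | None = None) -> pd.DataFrame:
        """Summaries of the lag coefficients, indexed by lag s = 1..S."""
        prefix = "lag" if kind is None else f"lag_{kind}"
        rows = [f"{prefix}[{s}]" for s in range(1, self.S + 1)]
        out = self.summary.loc[rows].copy()
        out.index = pd.RangeIndex(1, self.S + 1, name="s")
        return out


def _prior_sds(p_lag_cols: int, priors: Priors, ar: bool) -> np.ndarray:
    sds = [priors.intercept_sd] + [priors.lag_sd] * p_lag_cols
    if ar:
        sds.append(priors.ar_sd)
    return np.array(sds)


def _design_matrix(design: LagDesign, variant: str):
    if variant == "plain":
        X = np.hstack([np.ones((design.n, 1)), design.lags])
        names = ["intercept"] + [f"lag[{s}]" for s in range(1, design.S + 1)]
        keep = np.ones(design.n, dtype=bool)
        n_lag_cols = design.S
    elif variant == "split":
        X = np.hstack([np.ones((design.n, 1)), design.lags_hit, design.lags_nonhit])
        names = (["intercept"]
                 + [f"lag_hit[{s}]" for s in range(1, design.S + 1)]
                 + [f"lag_nonhit[{s}]" for s in range(1, design.S + 1)])
        keep = np.ones(design.n, dtype=bool)
        n_lag_cols = 2 * design.S
    elif variant == "ar1":
        keep = np.isfinite(design.prev_link)
        prev = design.prev_link[keep]
        prev = prev - prev.mean()      # centred so the intercept keeps its meaning
        X = np.hstack([np.ones((keep.sum(), 1)), design.lags[keep],
                       prev[:, None]])
        names = ["intercept"] + [f"lag[{s}]" for s in range(1, design.S + 1)] + ["rho"]
        n_lag_cols = design.S
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return X, names, keep, n_lag_cols


def _rw_penalty(coefs: np.ndarray, scale: float):
    """Random-walk smoothing prior on successive lag coefficients."""
    d = np.diff(coefs)
    val = -0.5 * np.sum((d / scale) ** 2)
    g = np.zeros_like(coefs)
    g[:-1] += d / scale**2
    g[1:] -= d / scale**2
    return val, g


def fit_beta_lag(design: LagDesign, priors: Priors | None = None,
                 sampler_cfg: SamplerConfig | None = None, seed: int = 0,
                 variant: str = "plain") -> LagFit:
    """Fit the lagged Beta regression of turning angle on encounters."""
    if design.kind != "delta":
        raise ValueError("fit_beta_lag expects a turning-angle design")
    priors = priors or Priors()
    cfg = sampler_cfg or SamplerConfig()
    X, names, keep, n_lag_cols = _design_matrix(design, variant)
    y = design.outcome[keep]
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("turning angles must lie strictly inside (0, 1)")
    logy, log1my = np.log(y), np.log1p(-y)
    sds = _prior_sds(n_lag_cols, priors, ar=variant == "ar1")
    rate = priors.dispersion_rate
    lag_sl = slice(1, 1 + n_lag_cols)

    def neg_logpost(par):
        coef, lognu = par[:-1], par[-1]
        nu = np.exp(lognu)
        eta = X @ coef
        mu = expit(eta)
        a, b = mu * nu, (1 - mu) * nu
        ll = np.sum(gammaln(nu) - gammaln(a) - gammaln(b)
                    + (a - 1) * logy + (b - 1) * log1my)
        dl_dmu = nu * (digamma(b) - digamma(a) + logy - log1my)
        g_coef = X.T @ (dl_dmu * mu * (1 - mu))
        dl_dnu = np.sum(digamma(nu) - mu * digamma(a) - (1 - mu) * digamma(b)
                        + mu * logy + (1 - mu) * log1my)
        g_lognu = nu * dl_dnu
        lp = ll - 0.5 * np.sum((coef / sds) ** 2) + (np.log(rate) - rate * nu) + lognu
        g_coef -= coef / sds**2
        g_lognu += -rate * nu + 1.0
        if priors.rw_scale is not None:
            pen, gpen = _rw_penalty(coef[lag_sl], priors.rw_scale)
            lp += pen
            g_coef[lag_sl] += gpen
        return -lp, -np.concatenate([g_coef, [g_lognu]])

    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = logit(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    x0[-1] = np.log(2.0)
    rng = np.random.default_rng(seed)

    def transform(d):
        out = d.copy()
        out[..., -1] = np.exp(out[..., -1])
        return out

    post = laplace_sample(neg_logpost, x0, names + ["nu"], cfg, rng, transform)
    return LagFit(model="beta", variant=variant, S=design.S, posterior=post)


def fit_lognormal_lag(design: LagDesign, priors: Priors | None = None,
                      sampler_cfg: SamplerConfig | None = None, seed: int = 0,
                      variant: str = "plain") -> LagFit:
    """Fit the lagged log-normal regression of step size on encounters."""
    if design.kind != "r":
        raise ValueError("fit_lognormal_lag expects a step-size design")
    priors = priors or Priors()
    cfg = sampler_cfg or SamplerConfig()
    X, names, keep, n_lag_cols = _design_matrix(design, variant)
    r = design.outcome[keep]
    if np.any(r <= 0):
        raise ValueError("step sizes must be positive after flooring")
    z = np.log(r)
    sds = _prior_sds(n_lag_cols, priors, ar=variant == "ar1")
    rate = priors.dispersion_rate
    lag_sl = slice(1, 1 + n_lag_cols)
    n = z.size

    def neg_logpost(par):
        coef, logw = par[:-1], par[-1]
        w = np.exp(logw)
        resid = z - X @ coef
        # LogNormal(r; eta, w): the -log r term is parameter-free
        ll = -n * logw - 0.5 * np.sum(resid**2) / w**2 - np.sum(z) \
            - 0.5 * n * np.log(2 * np.pi)
        g_coef = X.T @ resid / w**2
        g_logw = -n + np.sum(resid**2) / w**2
        lp = ll - 0.5 * np.sum((coef / sds) ** 2) + (np.log(rate) - rate * w) + logw
        g_coef -= coef / sds**2
        g_logw += -rate * w + 1.0
        if priors.rw_scale is not None:
            pen, gpen = _rw_penalty(coef[lag_sl], priors.rw_scale)
            lp += pen
            g_coef[lag_sl] += gpen
        return -lp, -np.concatenate([g_coef, [g_logw]])

    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = z.mean()
    x0[-1] = np.log(max(z.std(), 1e-2))
    rng = np.random.default_rng(seed)

    def transform(d):
        out = d.copy()
        out[..., -1] = np.exp(out[..., -1])
        return out

    post = laplace_sample(neg_logpost, x0, names + ["omega"], cfg, rng, transform)
    return LagFit(model="lognormal", variant=variant, S=design.S, posterior=post)


def fit_variants(design: LagDesign, variant: str,
                 priors: Priors | None = None,
                 sampler_cfg: SamplerConfig | None = None,
                 seed: int = 0) -> LagFit:
    """Robustness variants: 'ar1' (autoregressive control) or 'split'.

    The split variant requires encounter subtypes; it errors if none of
    the flagged encounters carry a hit/non-hit label.
    """
    if variant not in ("ar1", "split"):
        raise ValueError(f"unknown variant {variant!r}; use 'ar1' or 'split'")
    if variant == "split" and not (design.lags_hit.any() or design.lags_nonhit.any()):
        raise ValueError("split variant requires encounter annotations")
    if variant == "split" and not design.lags_hit.any():
        raise ValueError("split variant requires hit/non-hit encounter kinds")
    fitter = fit_beta_lag if design.kind == "delta" else fit_lognormal_lag
    return fitter(design, priors=priors, sampler_cfg=sampler_cfg, seed=seed,
                  variant=variant)


def first_crossing_lag(fit: LagFit, side: str = "above",
                       kind: str | None = None) -> int:
    """Smallest lag s whose 90% interval no longer excludes zero.

    ``side='above'`` asks for effects significantly greater than zero
    (turning angle), ``side='below'`` for significantly less (step
    size); effects are significant for every s strictly below the
    returned lag. Returns S + 1 when every interval excludes zero.
    """
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    lag = fit.lag_summary(kind)
    significant = lag["ci5"] > 0 if side == "above" else lag["ci95"] < 0
    not_sig = np.flatnonzero(~significant.to_numpy())
    return int(not_sig[0]) + 1 if not_sig.size else fit.S + 1
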