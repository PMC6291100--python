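"""Posterior computation helpers.

The lagged regression models have ~90 near-orthogonal coefficients and
thousands of observations, so their posteriors are very nearly Gaussian.
They are therefore fit by posterior-mode optimisation followed by a
Laplace (Gaussian) approximation: draws are sampled from
N(mode, H^-1) where H is the negative log-posterior Hessian at the mode.
This keeps a full fit to a few seconds while preserving a draws-based
interface (summaries, intervals, pointwise quantities) identical to what
an MCMC sampler would provide. Low-dimensional models with boundary
behaviour (the truncated step-size distributions) use MCMC instead; see
:mod:`ars_search.dist_fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class SamplerConfig:
    """Draw-count settings shared by all fitting routines.

    ``chains`` x ``draws`` posterior draws are produced (for the Laplace
    route the chain structure only controls the total draw count).
    """

    chains: int = 4
    draws: int = 1000
    warmup: int = 500          # used by the MCMC route only
    thin: int = 1

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws


@dataclass
class Posterior:
    """Posterior draws plus summaries for a named parameter vector."""

    param_names: list[str]
    draws: np.ndarray                  # (total_draws, p), natural scale
    mode: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        q = np.percentile(self.draws, [5.0, 50.0, 95.0], axis=0)
        return pd.DataFrame(
            {"median": q[1], "ci5": q[0], "ci95": q[2],
             "mean": self.draws.mean(axis=0), "sd": self.draws.std(axis=0)},
            index=pd.Index(self.param_names, name="param"),
        )


def _fd_hessian(grad, x, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function from its gradient."""
    p = x.size
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * max(1.0, abs(x[j]))
        e = np.zeros(p)
        e[j] = h
        H[:, j] = (grad(x + e) - grad(x - e)) / (2 * h)
    return 0.5 * (H + H.T)


def laplace_sample(neg_logpost, x0: np.ndarray, param_names: list[str],
                   cfg: SamplerConfig, rng: np.random.Generator,
                   transform=None) -> Posterior:
    """MAP optimisation + Gaussian draws from the local curvature.

    ``neg_logpost(x)`` must return ``(value, gradient)`` on the
    unconstrained scale. ``transform`` maps unconstrained draws to the
    natural parameter scale (identity if omitted).
    """
    res = optimize.minimize(neg_logpost, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000})
    mode = res.x
    grad_only = lambda x: neg_logpost(x)[1]
    H = _fd_hessian(grad_only, mode)

    # guard against indefinite curvature from finite differences
    jitter = 0.0
    for _ in range(8):
        try:
            L = np.linalg.cholesky(H + jitter * np.eye(H.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-8 * np.abs(np.diag(H)).max())
    else:  # pragma: no cover - pathological curvature
        raise RuntimeError("posterior Hessian not positive definite")

    z = rng.standard_normal((cfg.total_draws, mode.size))
    # draws = mode + H^{-1/2} z  via triangular solves
    draws_unc = mode + np.linalg.solve(L.T, z.T).T
    draws = transform(draws_unc) if transform is not None else draws_unc
    diag = {
        "converged": bool(res.success),
        "n_iter": int(res.nit),
        "grad_norm": float(np.linalg.norm(res.jac)),
        "hessian_jitter": float(jitter),
        "method": "laplace",
    }
    if not res.success:
        diag["warning"] = f"optimiser did not report convergence: {res.message}"
    return Posterior(param_names=list(param_names), draws=draws,
                     mode=transform(mode[None])[0] if transform else mode,
                     diagnostics=diag)
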