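"""Patch-conditional descriptive regressions.

A 'patch' is defined operationally: any step within W (default 50) ten-
second steps after a prey encounter. Two families of simple regressions
summarise patch behaviour:

* the effect of being in-patch on turning angle and step size — a linear
  regression on the in-patch indicator, whose slope is exactly the
  difference of in/out sample means; and
* the effect of last-step movement on encountering prey now — a logistic
  regression of the encounter flag at t on turning angle or step size at
  t - 1, slope on the log-odds scale.

Point estimates are maximum likelihood with central 90% Wald intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .kinematics import PatchLabels


@dataclass(frozen=True)
class PatchRegressionResult:
    predictor: str
    outcome: str
    beta: float
    ci_low: float
    ci_high: float
    model_form: str     # 'linear' or 'logistic'
    n: int

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")


def regress_on_patch(outcome_values, patch_labels: PatchLabels,
                     outcome_name: str = "outcome") -> PatchRegressionResult:
    """Linear regression of an outcome on the in-patch indicator.

    With a single binary regressor the slope equals the in-patch minus
    out-of-patch mean difference. NaN outcomes (undefined turns) are
    dropped together with their labels.
    """
    y = np.asarray(outcome_values, dtype=float)
    g = np.asarray(patch_labels.in_patch, dtype=float)
    if y.shape != g.shape:
        raise ValueError("outcome and patch labels must align")
    keep = np.isfinite(y)
    y, g = y[keep], g[keep]
    if g.min() == g.max():
        raise ValueError("degenerate contrast: all steps on one side of the patch label")
    fit = sm.OLS(y, sm.add_constant(g)).fit()
    lo, hi = fit.conf_int(alpha=0.10)[1]
    return PatchRegressionResult(
        predictor=f"in_patch(W={patch_labels.window})", outcome=outcome_name,
        beta=float(fit.params[1]), ci_low=float(lo), ci_high=float(hi),
        model_form="linear", n=int(y.size))


def encounter_regression(E, predictor_values, predictor_name: str = "predictor",
                         segment=None) -> PatchRegressionResult:
    """Logistic regression of the encounter flag on the lagged predictor.

    Pairs E[t] with the predictor at t - 1, never crossing a trip or
    cadence-segment boundary; rows with an undefined predictor (e.g. a
    stationary step's turning angle) are dropped.
    """
    E = np.asarray(E)
    x = np.asarray(predictor_values, dtype=float)
    if E.shape != x.shape:
        raise ValueError("encounter flags and predictor must align")
    seg = np.zeros(E.size, dtype=int) if segment is None else np.asarray(segment)
    same_seg = seg[1:] == seg[:-1]
    y_t = E[1:][same_seg].astype(float)
    x_tm1 = x[:-1][same_seg]
    keep = np.isfinite(x_tm1)
    y_t, x_tm1 = y_t[keep], x_tm1[keep]
    if y_t.sum() == 0:
        raise ValueError("no encounters in the data; logistic contrast undefined")
    fit = sm.Logit(y_t, sm.add_constant(x_tm1)).fit(disp=0)
    lo, hi = fit.conf_int(alpha=0.10)[1]
    return PatchRegressionResult(
        predictor=f"{predictor_name}[t-1]", outcome="E[t]",
        beta=float(fit.params[1]), ci_low=float(lo), ci_high=float(hi),
        model_form="logistic", n=int(y_t.size))
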