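"""Lag design assembly and the lagged Beta / log-normal fits."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from ars_search import (Priors, SamplerConfig, SimConfig, build_lag_design,
                        first_crossing_lag, fit_beta_lag, fit_lognormal_lag,
                        fit_variants)
from ars_search.forager_sim import (polar_series_from_draws,
                                    simulate_lag_model_tracks)
from conftest import make_recovery_sim


def _toy_series(E, delta=None, r=None, segment=None, kinds=None):
    n = len(E)
    ps = polar_series_from_draws("toy", np.asarray(E),
                                 np.full(n, 0.4) if delta is None else delta,
                                 np.full(n, 2.0) if r is None else r)
    if segment is not None:
        ps.segment = np.asarray(segment)
    if kinds is not None:
        ps.E_kind = np.asarray(kinds, dtype=object)
    return ps


def test_lag_matrix_rows():
    ps = _toy_series([0, 0, 1, 0])
    d = build_lag_design(ps, S=2)
    # row for t = 4 (index 3): lags are (E[3], E[2]) = (1, 0)
    assert list(d.lags[3]) == [1.0, 0.0]
    # first row of a trip: all lags refer to pre-trip time -> zero
    assert not d.lags[0].any()


def test_no_lag_carryover_across_trips_or_segments():
    a = _toy_series([0, 0, 0, 1])      # encounter at the very end of trip 1
    b = _toy_series([0, 0, 0, 0])
    d = build_lag_design([a, b], S=3)
    assert not d.lags[4:].any()
    seg = _toy_series([0, 1, 0, 0], segment=[0, 0, 1, 1])
    d2 = build_lag_design(seg, S=2)
    assert not d2.lags[2:].any()       # the gap resets the encounter history


def test_design_validation():
    ps = _toy_series([0, 1, 0, 0])
    with pytest.raises(ValueError, match="at least one lag"):
        build_lag_design(ps, S=0)
    with pytest.raises(ValueError, match="smaller than trip length"):
        build_lag_design(ps, S=4)
    with pytest.raises(ValueError, match="unknown outcome"):
        build_lag_design(ps, S=1, outcome="theta")


def test_beta_fit_matches_ml_when_no_encounters(fast_sampler):
    """With E == 0 the model is a two-parameter Beta; compare with MLE."""
    rng = np.random.default_rng(4)
    n = 4000
    delta = rng.beta(0.35 * 6.0, 0.65 * 6.0, n)
    ps = _toy_series(np.zeros(n, int), delta=delta,
                     r=rng.lognormal(0.5, 1.0, n))
    d = build_lag_design(ps, S=5)
    fit = fit_beta_lag(d, sampler_cfg=fast_sampler, seed=0)
    a_ml, b_ml, *_ = stats.beta.fit(delta, floc=0, fscale=1)
    mu_med = float(expit(fit.summary.loc["intercept", "median"]))
    nu_med = float(fit.summary.loc["nu", "median"])
    assert mu_med == pytest.approx(a_ml / (a_ml + b_ml), abs=0.02)
    assert nu_med == pytest.approx(a_ml + b_ml, rel=0.05)


def test_lognormal_fit_matches_ols_oracle(fast_sampler):
    """Flat-prior limit: posterior medians track the OLS fit of log r."""
    import statsmodels.api as sm

    polars, _, truth_phi = make_recovery_sim(seed=21, S=20, width=8,
                                             n_trips=2, n_steps=900)
    d = build_lag_design(polars, S=20, outcome="r")
    fit = fit_lognormal_lag(
        d, priors=Priors(lag_sd=100.0, intercept_sd=100.0),
        sampler_cfg=fast_sampler, seed=0)
    X = sm.add_constant(d.lags)
    ols = sm.OLS(np.log(d.outcome), X).fit()
    post_coef = fit.summary["median"].to_numpy()[: 21]
    assert np.allclose(post_coef, ols.params, atol=0.02)


def test_first_crossing_conventions():
    polars, *_ = make_recovery_sim(seed=31, S=12, width=12, psi_amp=2.0,
                                   n_trips=2, n_steps=600)
    d = build_lag_design(polars, S=12)
    fit = fit_beta_lag(d, sampler_cfg=SamplerConfig(chains=2, draws=300), seed=1)
    lag = fit.lag_summary()
    if (lag["ci5"] > 0).all():     # every interval excludes zero -> S + 1
        assert first_crossing_lag(fit, "above") == 13
    with pytest.raises(ValueError, match="side"):
        first_crossing_lag(fit, "sideways")


def test_ar1_variant_covers_zero_rho(fast_sampler):
    """Data generated without autocorrelation: rho's CI should cover 0."""
    covered = 0
    for seed in range(10):
        polars, *_ = make_recovery_sim(seed=100 + seed, S=15, width=6,
                                       n_trips=2, n_steps=700)
        d = build_lag_design(polars, S=15)
        fit = fit_variants(d, "ar1", sampler_cfg=fast_sampler, seed=seed)
        lo, hi = fit.summary.loc["rho", ["ci5", "ci95"]]
        covered += lo <= 0 <= hi
    assert covered >= 8


def test_split_variant_equal_effects_overlap(fast_sampler):
    """Hit and non-hit curves fitted to data with a single common effect."""
    rng = np.random.default_rng(7)
    cfg = SimConfig(n_trips=3, n_steps=900,
                    psi=np.where(np.arange(1, 16) <= 6, 1.0, 0.0),
                    phi=np.zeros(15), seed=7)
    trips = simulate_lag_model_tracks(cfg, seed=7)
    polars = []
    for i, (E, delta, r) in enumerate(trips):
        ps = polar_series_from_draws(f"t{i}", E, delta, r)
        kinds = np.where(E == 1,
                         np.where(rng.random(E.size) < 0.5, "hit", "nonhit"),
                         "none")
        ps.E_kind = kinds.astype(object)
        polars.append(ps)
    d = build_lag_design(polars, S=15)
    fit = fit_variants(d, "split", sampler_cfg=fast_sampler, seed=3)
    hit = fit.lag_summary("hit")
    non = fit.lag_summary("nonhit")
    overlap = np.mean((hit["ci5"] <= non["ci95"]) & (non["ci5"] <= hit["ci95"]))
    assert overlap >= 0.8


def test_split_requires_kinds():
    ps = _toy_series([0, 1, 0, 0, 0, 0])
    d = build_lag_design(ps, S=2)
    with pytest.raises(ValueError, match="hit/non-hit"):
        fit_variants(d, "split")
    with pytest.raises(ValueError, match="unknown variant"):
        fit_variants(d, "bootstrap")


def test_plain_vs_ar1_sign_pattern_stable(fast_sampler):
    """Robustness: adding the AR-1 control keeps the significant signs."""
    polars, *_ = make_recovery_sim(seed=55, S=20, width=10, psi_amp=1.2,
                                   phi_amp=-0.8, n_trips=3, n_steps=900)
    for outcome, fitter, side in (("delta", fit_beta_lag, "above"),
                                  ("r", fit_lognormal_lag, "below")):
        d = build_lag_design(polars, S=20, outcome=outcome)
        plain = fitter(d, sampler_cfg=fast_sampler, seed=0)
        ar1 = fitter(d, sampler_cfg=fast_sampler, seed=0, variant="ar1")
        sig = lambda f: ((f.lag_summary()["ci5"] > 0) if side == "above"
                         else (f.lag_summary()["ci95"] < 0)).to_numpy()
        agree = np.mean(sig(plain) == sig(ar1))
        assert agree >= 0.85


def test_posterior_mu_scale_in_unit_interval(recovery_polars, fast_sampler):
    polars, truth_psi, _ = recovery_polars
    d = build_lag_design(polars, S=90)
    fit = fit_beta_lag(d, sampler_cfg=fast_sampler, seed=2)
    mu0 = expit(fit.posterior.draws[:, 0])
    assert np.all((mu0 > 0) & (mu0 < 1))
    assert np.all(fit.posterior.draws[:, -1] > 0)   # nu positive in every draw
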