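# ars-search

Encounter-conditional analysis of forager GPS tracks.

Foraging theory offers two contrasting accounts of how a predator should
search for prey. Under the Lévy flight foraging hypothesis the forager
moves with uniformly distributed turning angles and heavy-tailed
(power-law) step lengths regardless of what it finds. Under
encounter-conditional, **area-restricted search (ARS)** the forager uses
prey encounters as information: just after an encounter it turns more
sharply and slows down — concentrating effort where prey were found —
and after a long dry spell it straightens out and speeds up to travel
between patches. Telling these apart requires *event-level* data: GPS
tracks annotated with the times of individual prey encounters.

`ars-search` implements the full analysis chain for such data, plus a
simulator so the chain can be exercised (and its calibration verified)
without field data:

* **track_io** — GPX track and encounter-annotation reading/writing,
  local tangent-plane projection, per-hunt descriptive statistics.
* **kinematics** — polar step series: step size
  `r[t] = ||(x,y)[t] − (x,y)[t−1]||` (meters per 10 s fix, a velocity
  proxy), heading `θ[t] ∈ (−π, π]` from the quadrant-adjusted
  arctangent, and unit-scaled turning angle
  `δ[t] = min(|θ[t]−θ[t−1]|, 2π−|θ[t]−θ[t−1]|)/π ∈ [0, 1]`;
  patch labelling (within W = 50 steps after an encounter).
* **lagged_bayes** — the central models. Turning angle:
  `δ[t] ~ Beta(μ[t]ν, (1−μ[t])ν)` with
  `μ[t] = logit⁻¹(ψ₀ + Σₛ ψ[s]·E[t−s])`; step size:
  `r[t] ~ LogNormal(η[t], ω)` with `η[t] = φ₀ + Σₛ φ[s]·E[t−s]`,
  where `E[t−s]` flags an encounter s steps earlier (s = 1..90 by
  default). ARS predicts ψ[s] > 0 and φ[s] < 0 at short lags; a
  non-conditional Lévy searcher is the special case ψ ≡ 0, ν = 2.
  AR-1 and encounter-type-split robustness variants, and the "first
  crossing" lag at which the 90% credible intervals reach zero.
* **dist_fit** — six candidate step-size distributions (folded normal,
  log-normal, Pareto; plain and upper-truncated) compared by WAIC with
  Akaike weights.
* **patch_stats** — simple patch-conditional regressions: the effect of
  being in-patch on δ and r, and logistic regressions of the encounter
  flag on last-step δ and r.
* **forager_sim** — synthetic data: the lag model run generatively, an
  ARS agent in a Thomas-cluster prey field (encounters feed back into
  movement), and a truncated-Pareto Lévy walker.

## Worked example

```python
import numpy as np
from ars_search import (SimConfig, simulate_forager, to_polar,
                        build_lag_design, fit_beta_lag, fit_lognormal_lag,
                        first_crossing_lag, SamplerConfig)

sim = simulate_forager(SimConfig(seed=1), mode="ars", seed=1)   # 6 trips x 1100 steps
polars = [to_polar(t) for t in sim.tracks]
print(sum(int(t.E.sum()) for t in sim.tracks))                  # 96 encounters

cfg = SamplerConfig(chains=2, draws=500)
beta = fit_beta_lag(build_lag_design(polars, S=90, outcome="delta"),
                    sampler_cfg=cfg, seed=1)
logn = fit_lognormal_lag(build_lag_design(polars, S=90, outcome="r"),
                         sampler_cfg=cfg, seed=2)
print(first_crossing_lag(beta, "above"), first_crossing_lag(logn, "below"))
# 49 42
```

The two numbers are the lags (in 10 s steps) up to which encounters
demonstrably change movement: here turning angle stays elevated for
49 steps (~8 minutes) after an encounter and step size stays depressed
for 42 steps (~7 minutes) — the ARS signature. On a Lévy simulation
(`mode="levy"`) both effect curves are flat and the fitted Beta
intercept concentrates at a mean turning angle of 0.5 with ν ≈ 2, the
uniform distribution.

The same pipeline runs from the shell on GPX files:

```sh
ars-search simulate --mode ars --seed 1 --out tracks/
ars-search run --tracks tracks/ --lags 90 --patch-window 50 --seed 1 --out report/
```

`report/` then contains per-hunt descriptives, the two lag-effect
posterior tables and plot, the first-crossing lags, the six-model WAIC
table and the patch regressions.

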