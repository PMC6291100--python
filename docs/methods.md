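# Methods

## The question and the data model

A forager's GPS track at a fixed 10 s cadence is reduced to a polar step
series: step size `r[t]` (meters per fix interval; at constant cadence a
velocity proxy), heading `θ[t] ∈ (−π, π]` (quadrant-adjusted arctangent
of the displacement, i.e. `atan2`), and unit-scaled turning angle
`δ[t] = min(|θ[t]−θ[t−1]|, 2π−|θ[t]−θ[t−1]|)/π`, which identifies a
right turn of x with a left turn of 2π−x and puts straight travel at 0
and reversal at 1. Sparse binary encounter flags `E[t]` mark fixes at
which a prey item was detected (optionally subtyped hit / non-hit).

The behavioural question — does the forager condition movement on
encounters? — is posed as a pair of lagged regressions over an
encounter history of S steps (default S = 90, i.e. 15 minutes):

    δ[t] ~ Beta(μ[t]ν, (1−μ[t])ν),   μ[t] = logit⁻¹(ψ₀ + Σₛ ψ[s] E[t−s])
    r[t] ~ LogNormal(η[t], ω),        η[t] = φ₀ + Σₛ φ[s] E[t−s]

Area-restricted search appears as ψ[s] > 0 and φ[s] < 0 at short lags,
decaying as the information from the encounter ages. A non-conditional
Lévy searcher is nested as ψ₀ = 0, ψ[s] = 0, ν = 2 (uniform turning
angles) with heavy-tailed steps. The "significance run" summary —
`first_crossing_lag` — is the smallest lag s at which the central 90%
credible interval for ψ[s] (or φ[s]) no longer excludes zero; effects
are credibly nonzero for every lag before it.

## Priors, inference, and why Laplace

Priors are weakly informative: Normal(0, 5) on the intercepts ψ₀, φ₀,
Normal(0, 1) on each lag coefficient and the AR-1 coefficient,
Exponential(rate 0.1) on the positive dispersions ν and ω. Lag
coefficients are a-priori independent; a random-walk smoothing prior
across s is available (`Priors.rw_scale`) but off by default, since
independence is the more conservative default and at n ≈ 6,600 the data
dominate either way.

The lag models have ~92 parameters, thousands of observations, and
smooth log-concave-like posteriors; their Bayesian fits use posterior-
mode optimisation (L-BFGS with analytic gradients) followed by a Laplace
approximation — draws from N(mode, H⁻¹) with H the negative
log-posterior Hessian (finite differences of the analytic gradient).
This keeps a full fit under a second while exposing the same
draws-based interface as a sampler. The calibration of this
approximation is itself under test: the suite checks ~90% empirical
coverage of the 90% intervals in parameter-recovery simulations and a
~10% false-exclusion rate under the null. The low-dimensional step-size
distribution models are instead sampled with emcee's affine-invariant
ensemble MCMC, because the truncation point τ has a boundary-peaked
posterior (its likelihood is maximised at τ = max r) where a Gaussian
approximation is invalid.

Numerical conventions:

* **Stationary steps.** Displacements under ε = 0.5 m per 10 s (below
  GPS noise) have no meaningful heading; the heading is left undefined
  and the last valid heading is carried forward so the next moving step
  still yields a turn. Turning angles with no defined predecessor
  heading are dropped from likelihoods.
* **Endpoint squeeze.** The Beta density is undefined at exactly 0
  and 1, so turning angles are compressed by d′ = (d(n−1) + 0.5)/n
  (n = number of turning angles) before likelihood evaluation.
* **Zero step sizes.** Step sizes are floored at 0.05 m (half the
  stationarity threshold) before the log-normal likelihood, so resting
  fixes contribute a well-defined small step rather than log 0.
* **Cadence gaps.** Fixes are expected 10 s apart (±2 s jitter
  tolerated). A gap of more than one missed fix splits the series into
  segments; lag matrices, AR-1 terms, patch labels and encounter
  regressions never cross a segment or trip boundary, and lags
  referring to pre-trip time are zero.
* **AR-1 variant.** The link-scale previous outcome (logit of the
  squeezed δ[t−1], or log r[t−1]), centred, enters the linear predictor
  with coefficient ρ — an observation-driven autoregression that
  absorbs short-range temporal correlation. The split variant
  duplicates the lag curve per encounter subtype (hit vs non-hit),
  since post-capture handling may differ from continued search.

## Step-size distribution comparison

Six models for the pooled step sizes: folded normal, log-normal and
Pareto, each plain and upper-truncated (density renormalised as
f(x)/F(τ) on x ≤ τ). τ is estimated, with a Uniform[max r, 2·max r]
prior; the Pareto lower bound is fixed at the smallest (floored)
observation. Remaining priors: Normal(0, 5) on location, Exponential(1)
on scale and on the Pareto shape. Models are ranked by WAIC on the
deviance scale, WAIC = −2(lppd − p_waic) with
lppd = Σᵢ log meanₔ exp ll[d,i] and p_waic = Σᵢ varₔ ll[d,i], computed
from the pointwise log-likelihood matrix over retained draws; Akaike
weights are exp(−ΔWAIC/2), normalised. A heavy-tailed (Pareto-family)
winner is what the Lévy hypothesis predicts; the ARS mixture of slow
in-patch and fast inter-patch movement instead favours log-normal-type
shapes.

## Patch statistics

A *patch* is defined operationally as the union of the W = 50 steps
following each encounter (the encounter step itself excluded, within
trip/segment only). The in-patch effect on δ and r is a linear
regression on the indicator — with a single binary regressor the slope
is exactly the in/out mean difference — and the effect of last-step
movement on encountering prey is a univariate logistic regression of
E[t] on δ[t−1] or r[t−1]. These are deliberately plain maximum-
likelihood fits (statsmodels OLS/Logit) with central 90% Wald
intervals: they are descriptive summaries, not the inferential core.

## The simulator: what it emulates and what it does not

Defaults reproduce the structure of the motivating field study: 6 trips
of 1,100 steps at 10 s (≈ 6,600 fixes), encounters at ≈ 1.5% of fixes,
out-of-patch mean turning angle ≈ 0.2 (logit⁻¹(−1.4)), out-of-patch
median step ≈ 2.2 m/10 s (φ₀ = 0.8, ω = 1), and effect curves decaying
over ≈ 30 lags (ψ*ₛ = 1.5·e^(−s/30), φ*ₛ = −0.9·e^(−s/30)). The prey
field is a Thomas cluster process — Poisson(κ·area) cluster centres,
Poisson(m̄) items per cluster, Gaussian scatter σ_c — with κ = 35 /km²,
m̄ = 16, σ_c = 25 m and a 15 m detection radius over a 1 km² arena,
which yields the target ≈ 1.5% encounter prevalence in ARS mode; these
were fixed once when the generator was built. The ARS agent draws its
turn magnitude and step from the lag model given its own realised
encounter history (turn direction ±, arena walls reflecting); the Lévy
agent draws uniform headings and truncated-Pareto steps (α = 2,
x ∈ [1, 200] m by default; truncation keeps paths finite) and ignores
encounters. Encountered prey are removed.

Simulations are not field data: the generative mode realises the
fitted model exactly (so recovery tests verify inference, not the
behavioural theory); the agent modes have no terrain, no route
fidelity, no observer error, no memory beyond the S-step window, and
Bernoulli rather than spatially clustered exogenous encounters in the
generative mode. Passing tests therefore demonstrate that the pipeline
measures what it claims on data with this structure — not that real
foragers behave this way.

## Problem sizes and test design

The suite's simulation studies use the default 6 × 1,100-step
conditions for recovery and null calibration (20 and 3 seeds
respectively, with 2 chains × 500 draws), n = 10⁴ for distribution
parameter recovery, n = 5,000 per family for model-selection
consistency (one seed per family — the WAIC margins at that size make
extra replicates uninformative), and smaller tracks for the agent-based
property checks. `scripts/acceptance.py` recomputes every headline
quantity from scratch at the default conditions in about half a minute.

## Known limitations

* Laplace intervals are symmetric on the unconstrained scale; for
  strongly skewed posteriors (tiny effective sample per coefficient)
  they can under- or over-cover. The dispersion parameters are sampled
  on the log scale, which removes most of the skew.
* The planar projection is a spherical azimuthal-equidistant tangent
  plane; over the ≤ 10 km spans intended, distance distortion is far
  below GPS noise, but continental-scale tracks would need a geodesic
  treatment.
* Wald intervals in the logistic patch regressions can be unstable with
  very few encounters; the fitter raises on zero encounters but does
  not switch to exact methods for near-degenerate data.
* The hit / non-hit subtype in the simulator is assigned by an
  independent coin flip, so split-variant tests check only that the
  machinery separates the curves, not any behavioural difference.
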