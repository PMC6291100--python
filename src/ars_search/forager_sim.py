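"""Synthetic encounter-annotated forager tracks.

Three generators, sharing one configuration:

* ``simulate_from_lag_model`` — the inferential model run generatively:
  given an exogenous encounter sequence, draw turning angles from the
  lagged Beta model and step sizes from the lagged log-normal model.
  Used for parameter-recovery and calibration studies.

* ``simulate_forager(mode='ars')`` — an agent applying encounter-
  conditional (area-restricted) search heuristics in a patchy prey
  field: after an encounter it turns more and slows down, with the
  effect decaying over lags; far from encounters it travels fast and
  straight. Prey are laid down by a Thomas cluster process and removed
  when encountered, so encounters feed back into movement.

* ``simulate_forager(mode='levy')`` — a non-conditional Levy walker:
  uniform turning angles and truncated-Pareto step lengths; encounters
  are recorded but never alter movement.

Defaults emulate the structure of the motivating field data: 6 trips of
~1,100 fixes at a 10 s cadence with encounters at roughly 1.5% of fixes,
unit-interval turning angles whose mean rises after encounters, and
log-normal step sizes whose log-mean falls after encounters, both
decaying over tens of lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
from scipy.special import expit

from .projection import LocalProjection
from .track_io import CADENCE_S, Track


def exp_decay_curve(amplitude: float, decay: float, S: int) -> np.ndarray:
    """Smooth lag-effect curve a * exp(-s / decay), s = 1..S."""
    s = np.arange(1, S + 1)
    return amplitude * np.exp(-s / decay)


def step_curve(amplitude: float, width: int, S: int) -> np.ndarray:
    """Lag-effect curve equal to ``amplitude`` for s <= width, else 0."""
    s = np.arange(1, S + 1)
    return np.where(s <= width, amplitude, 0.0)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Movement parameters mirror the inferential model: ``psi0``/``psi``
    control the (logit-scale) mean turning angle and its response to
    lagged encounters; ``phi0``/``phi`` the log-scale mean step size
    (m per 10 s); ``nu``/``omega`` the dispersions. The prey field is a
    Thomas cluster process (``kappa`` cluster centres per km^2, Poisson
    ``mbar`` items per cluster, Gaussian scatter ``sigma_c`` m) over a
    square arena; prey within ``detect_radius`` m of the forager are
    encountered.
    """

    n_trips: int = 6
    n_steps: int = 1100
    # true lag-effect curves (defaults: exponential decays over ~30 lags)
    psi: np.ndarray = field(default_factory=lambda: exp_decay_curve(1.5, 30.0, 90))
    phi: np.ndarray = field(default_factory=lambda: exp_decay_curve(-0.9, 30.0, 90))
    psi0: float = -1.4          # logit^-1(-1.4) ~ 0.20 mean out-of-patch turn
    phi0: float = 0.8           # exp(0.8) ~ 2.2 m per 10 s out-of-patch
    nu: float = 5.0
    omega: float = 1.0
    # prey field
    arena_km: float = 1.0       # side of the square arena
    kappa: float = 35.0         # cluster centres per km^2
    mbar: float = 16.0          # mean prey per cluster
    sigma_c: float = 25.0       # cluster scatter (m)
    detect_radius: float = 15.0
    hit_prob: float = 0.13      # share of encounters where prey is shot & hit
    # exogenous encounter rate for the generative lag model
    encounter_prob: float = 98 / 6731
    # Levy movement
    levy_alpha: float = 2.0
    levy_xmin: float = 1.0
    levy_xmax: float = 200.0    # upper truncation keeping simulations finite
    seed: int = 0

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.psi.shape != self.phi.shape:
            raise ValueError("psi and phi lag curves must have equal length")
        if self.nu <= 0 or self.omega <= 0:
            raise ValueError("dispersion parameters nu and omega must be positive")
        if self.levy_alpha <= 1:
            raise ValueError("Levy exponent must exceed 1 for a normalizable tail")
        for name in ("kappa", "mbar", "sigma_c", "detect_radius", "arena_km"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def S(self) -> int:
        return self.psi.size


@dataclass
class SimResult:
    """Simulated tracks plus the ground truth that generated them."""

    tracks: list[Track]
    config: SimConfig
    mode: str
    prey_xy: np.ndarray | None = None          # remaining + encountered prey
    truth: dict = field(default_factory=dict)


def gen_prey_field(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Thomas cluster process over the arena, coordinates in meters.

    Parent centres are Poisson(kappa * area) over the square; each parent
    spawns Poisson(mbar) offspring scattered N(0, sigma_c^2) about it.
    Expected prey count is kappa * area * mbar.
    """
    side = config.arena_km * 1000.0
    area_km2 = config.arena_km**2
    n_parents = rng.poisson(config.kappa * area_km2)
    if n_parents == 0:
        return np.empty((0, 2))
    parents = rng.uniform(-side / 2, side / 2, size=(n_parents, 2))
    counts = rng.poisson(config.mbar, size=n_parents)
    offspring = np.repeat(parents, counts, axis=0)
    offspring = offspring + rng.normal(0.0, config.sigma_c, size=offspring.shape)
    return offspring


def _lag_effect(curve: np.ndarray, E: np.ndarray, t: int) -> float:
    """sum_s curve[s] * E[t-s] for one step, within-trip history only."""
    S = curve.size
    lo = max(0, t - S)
    if t == lo:
        return 0.0
    hist = E[lo:t][::-1]          # hist[0] = E[t-1]
    return float(curve[: hist.size] @ hist)


def simulate_from_lag_model(config: SimConfig, E_sequence: np.ndarray,
                            seed: int | None = None):
    """Draw (delta, r) series from the lag model given encounters.

    Returns ``(delta, r)`` arrays matching ``E_sequence``; the sequence
    is treated as a single trip (no lag carry-over is assumed outside).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    E = np.asarray(E_sequence, dtype=float)
    n = E.size
    # vectorised lag sums via correlation with the truth curves
    psi_sum = np.zeros(n)
    phi_sum = np.zeros(n)
    for s in range(1, config.S + 1):
        if s >= n:
            break
        psi_sum[s:] += config.psi[s - 1] * E[:-s]
        phi_sum[s:] += config.phi[s - 1] * E[:-s]
    mu = expit(config.psi0 + psi_sum)
    eta = config.phi0 + phi_sum
    delta = rng.beta(mu * config.nu, (1 - mu) * config.nu)
    r = rng.lognormal(mean=eta, sigma=config.omega)
    return delta, r


def gen_encounter_sequence(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Exogenous sparse Bernoulli encounter flags for one trip."""
    return (rng.random(config.n_steps) < config.encounter_prob).astype(np.int8)


def sample_truncated_pareto(alpha: float, xmin: float, xmax: float,
                            size, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from a Pareto(alpha) truncated to [xmin, xmax]."""
    u = rng.random(size)
    a = alpha
    # CDF of truncated Pareto: (1 - (xmin/x)^a) / (1 - (xmin/xmax)^a)
    c = 1.0 - (xmin / xmax) ** a
    return xmin * (1.0 - u * c) ** (-1.0 / a)


def _track_from_steps(trip_id: str, xy: np.ndarray, E_steps: np.ndarray,
                      kinds: np.ndarray, start: datetime) -> Track:
    n_fix = xy.shape[0]
    E = np.zeros(n_fix, dtype=np.int8)
    kind = np.full(n_fix, "none", dtype=object)
    E[1:] = E_steps            # an encounter on step t flags the arrival fix
    kind[1:] = kinds
    proj = LocalProjection(-75.9, 5.1)   # arbitrary tropical-forest origin
    lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
    return Track(
        trip_id=trip_id,
        t=np.arange(n_fix, dtype=float) * CADENCE_S,
        xy=xy,
        lonlat=np.column_stack([lon, lat]),
        E=E, E_kind=kind,
        projection=proj,
        start_time=start,
    )


def simulate_forager(config: SimConfig, mode: str = "ars",
                     seed: int | None = None) -> SimResult:
    """Simulate trips of an ARS or Levy forager through a prey field."""
    if mode not in ("ars", "levy"):
        raise ValueError(f"unknown mode {mode!r}; use 'ars' or 'levy'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    side = config.arena_km * 1000.0
    half = side / 2.0
    t0 = datetime(2017, 3, 1, 6, 0, tzinfo=timezone.utc)

    tracks: list[Track] = []
    prey_record = []
    for trip in range(config.n_trips):
        prey = gen_prey_field(config, rng)
        taken = np.zeros(prey.shape[0], dtype=bool)
        pos = rng.uniform(-half / 2, half / 2, size=2)
        heading = rng.uniform(-np.pi, np.pi)
        E = np.zeros(config.n_steps, dtype=np.int8)
        kinds = np.full(config.n_steps, "none", dtype=object)
        xy = np.empty((config.n_steps + 1, 2))
        xy[0] = pos

        for t in range(config.n_steps):
            if mode == "ars":
                mu = expit(config.psi0 + _lag_effect(config.psi, E, t))
                eta = config.phi0 + _lag_effect(config.phi, E, t)
                delta = rng.beta(mu * config.nu, (1 - mu) * config.nu)
                heading = heading + rng.choice((-1.0, 1.0)) * delta * np.pi
                r = rng.lognormal(mean=eta, sigma=config.omega)
            else:
                heading = rng.uniform(-np.pi, np.pi)
                r = sample_truncated_pareto(config.levy_alpha, config.levy_xmin,
                                            config.levy_xmax, None, rng)
            pos = pos + r * np.array([np.cos(heading), np.sin(heading)])
            # reflect at the arena walls
            for k in range(2):
                if pos[k] > half:
                    pos[k] = 2 * half - pos[k]
                elif pos[k] < -half:
                    pos[k] = -2 * half - pos[k]
                else:
                    continue
                heading = (np.pi - heading) if k == 0 else -heading
            xy[t + 1] = pos

            if prey.size:
                free = ~taken
                d2 = np.sum((prey[free] - pos) ** 2, axis=1)
                near = d2 <= config.detect_radius**2
                if near.any():
                    E[t] = 1
                    kinds[t] = "hit" if rng.random() < config.hit_prob else "nonhit"
                    idx = np.flatnonzero(free)[np.argmin(d2)]
                    taken[idx] = True     # encountered prey item is removed

        tracks.append(_track_from_steps(
            f"sim-{mode}-{trip + 1}", xy, E, kinds,
            t0 + timedelta(days=trip)))
        prey_record.append(prey)

    truth = {"psi0": config.psi0, "psi": config.psi.copy(),
             "phi0": config.phi0, "phi": config.phi.copy(),
             "nu": config.nu, "omega": config.omega, "mode": mode}
    return SimResult(tracks=tracks, config=config, mode=mode,
                     prey_xy=np.vstack(prey_record) if prey_record else None,
                     truth=truth)


def polar_series_from_draws(trip_id: str, E: np.ndarray, delta: np.ndarray,
                            r: np.ndarray):
    """Wrap generative (E, delta, r) draws as a single-segment PolarSeries."""
    from .kinematics import PolarSeries
    n = np.asarray(E).size
    return PolarSeries(
        trip_id=trip_id, r=np.asarray(r, float), theta=np.zeros(n),
        delta=np.asarray(delta, float),
        E=np.asarray(E, np.int8),
        E_kind=np.where(np.asarray(E) == 1, "nonhit", "none"),
        valid_theta=np.ones(n, bool), valid_delta=np.ones(n, bool),
        segment=np.zeros(n, int))


def simulate_lag_model_tracks(config: SimConfig, seed: int | None = None):
    """Per-trip (E, delta, r) draws from the generative lag model.

    Returns a list of ``(E, delta, r)`` tuples, one per trip, with
    exogenous Bernoulli encounter sequences — the standard input for
    parameter-recovery and null-calibration studies.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for _ in range(config.n_trips):
        E = gen_encounter_sequence(config, rng)
        delta, r = simulate_from_lag_model(
            config, E, seed=int(rng.integers(2**31 - 1)))
        out.append((E, delta, r))
    return out
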