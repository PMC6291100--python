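import numpy as np
import pytest

from ars_search import SamplerConfig, SimConfig
from ars_search.forager_sim import (polar_series_from_draws,
                                    simulate_lag_model_tracks, step_curve)

GPX_3PT = """<?xml version="1.0" encoding="UTF-8"?>
<gpx xmlns="http://www.topografix.com/GPX/1/1" version="1.1" creator="test">
 <trk><name>mini</name><trkseg>
  <trkpt lat="5.1000" lon="-75.9000"><ele>1500.0</ele><time>2017-03-01T06:00:00Z</time></trkpt>
  <trkpt lat="5.10005" lon="-75.9000"><ele>1501.0</ele><time>2017-03-01T06:00:10Z</time></trkpt>
  <trkpt lat="5.10010" lon="-75.90005"><ele>1502.5</ele><time>2017-03-01T06:00:20Z</time></trkpt>
 </trkseg></trk>
</gpx>
"""

GPX_UNTIMED = """<?xml version="1.0" encoding="UTF-8"?>
<gpx xmlns="http://www.topografix.com/GPX/1/1" version="1.1" creator="test">
 <trk><trkseg>
  <trkpt lat="5.1" lon="-75.9"><time>2017-03-01T06:00:00Z</time></trkpt>
  <trkpt lat="5.2" lon="-75.9"></trkpt>
 </trkseg></trk>
</gpx>
"""


@pytest.fixture
def gpx_3pt():
    return GPX_3PT


@pytest.fixture
def gpx_untimed():
    return GPX_UNTIMED


@pytest.fixture(scope="session")
def fast_sampler():
    return SamplerConfig(chains=2, draws=500)


@pytest.fixture(scope="session")
def mcmc_sampler():
    return SamplerConfig(chains=4, draws=250, warmup=200)


def make_recovery_sim(seed, S=90, width=40, psi_amp=0.8, phi_amp=-0.6,
                      n_trips=6, n_steps=1100):
    """Generative lag-model trips with known step-shaped effect curves."""
    cfg = SimConfig(n_trips=n_trips, n_steps=n_steps,
                    psi=step_curve(psi_amp, width, S),
                    phi=step_curve(phi_amp, width, S), seed=seed)
    trips = simulate_lag_model_tracks(cfg, seed=seed)
    polars = [polar_series_from_draws(f"trip-{i}", *t)
              for i, t in enumerate(trips)]
    truth_psi = np.where(np.arange(1, S + 1) <= width, psi_amp, 0.0)
    truth_phi = np.where(np.arange(1, S + 1) <= width, phi_amp, 0.0)
    return polars, truth_psi, truth_phi


@pytest.fixture(scope="session")
def recovery_polars():
    return make_recovery_sim(seed=11)
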