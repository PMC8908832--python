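import numpy as np
import pandas as pd
import pytest

from flocknet.curation import build_series_array, pair_registrations
from flocknet.synthetic import SimConfig, simulate_flock

EVENT_COLUMNS = ["day", "time_s", "hen_id", "antenna_id"]


def events_frame(rows):
    """Build a raw event log from (day, time_s, hen_id, antenna_id) tuples."""
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@pytest.fixture(scope="session")
def demo_sim():
    """One moderately coupled heterogeneous pen, shared across tests."""
    cfg = SimConfig(n_hens=24, n_days=10, s=0.6, seed=42)
    events, truth = simulate_flock(cfg)
    transitions = pair_registrations(events, truth.hens)
    series = build_series_array(transitions, truth.hens, cfg.n_days, 300, cfg.day_length)
    return cfg, events, truth, transitions, series


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
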