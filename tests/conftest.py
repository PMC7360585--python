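import datetime as dt

import numpy as np
import pytest

from cytoharm import EventMatrix, detect_peaks
from cytoharm.synthetic import SimulationConfig, simulate_beads

D0 = dt.date(2015, 1, 1)


@pytest.fixture(scope="session")
def clean_cfg():
    """Generator config with no instrument/lot/spillover effects."""
    return SimulationConfig(seed=11, daily_drift_sd=0.0,
                            with_spillover=False,
                            residual_center_effect_range=(1.0, 1.0))


@pytest.fixture(scope="session")
def unity(clean_cfg):
    return {m: 1.0 for m in clean_cfg.panel.markers}


@pytest.fixture(scope="session")
def reference_beads(clean_cfg, unity):
    return simulate_beads(clean_cfg, "INST01", D0, gain=unity, drift=1.0)


@pytest.fixture(scope="session")
def reference_peaks(reference_beads):
    return detect_peaks(reference_beads)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_event_matrix(rng, n_events=100, channels=("FSC", "SSC", "CD3"),
                      meta=None):
    values = rng.uniform(10.0, 1e4, size=(n_events, len(channels)))
    return EventMatrix(values, list(channels),
                       meta or {"instrument_id": "NAVIOS-1",
                                "acquisition_date": D0,
                                "sample_id": "S1", "panel_id": "panel1"})
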