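import numpy as np
import pytest

from pinchpoint.config import PipelineConfig
from pinchpoint.pipeline import process_trip
from pinchpoint.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-seal cohort, reduced interior, for fast unit tests."""
    return simulate_cohort(SimConfig(seed=42, n_seals=2, n_dives=60))


@pytest.fixture(scope="session")
def processed_small(small_cohort):
    """Small cohort run through detection/geolocation/classification."""
    cfg = PipelineConfig()
    out = []
    for trip in small_cohort.trips:
        res = process_trip(trip, small_cohort, cfg)
        res["trip"] = trip
        res["truth"] = trip.truth[~trip.truth.subthreshold].reset_index(drop=True)
        out.append(res)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
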