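import numpy as np
import pytest

from openfieldkit.config import AnalysisConfig, DefaultsConfig
from openfieldkit.synthetic import ExplorerParams, make_cohort
from openfieldkit.track_io import StandardTrack


@pytest.fixture
def sim_config() -> AnalysisConfig:
    """Analysis settings matched to the 1 Hz synthetic cohort."""
    return AnalysisConfig(
        groups_and_types={"A": "generic", "B": "generic"},
        arena_radius_cm=4.2, sample_freq=1.0, edge_dist_cm=1.0,
        time_bin_size=1.0, inactivity_threshold=0.05)


@pytest.fixture
def coarse_defaults() -> DefaultsConfig:
    """24-sector defaults for tests that count visits by hand."""
    return DefaultsConfig(node_size=15.0)


@pytest.fixture
def defaults() -> DefaultsConfig:
    return DefaultsConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Ten short explorer tracks with ground truth (shared across tests)."""
    params = ExplorerParams(duration_s=300.0, seed=0)
    return make_cohort(10, params, between_individual_sd=0.15, seed=11,
                       group="A")


def make_track(x, y, period=1.0, radius=4.2, group="t", uid="t0"):
    x = np.asarray(x, dtype=float)
    return StandardTrack(group=group, arena="a", arena_radius_cm=radius,
                         t=np.arange(len(x)) * period, x=x,
                         y=np.asarray(y, dtype=float), uid=uid)


@pytest.fixture
def track_factory():
    return make_track
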