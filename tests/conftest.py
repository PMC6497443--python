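import numpy as np
import pytest

from colonystate.geometry import four_chamber_nest, one_chamber_nest
from colonystate.preprocess import IN_NEST, AntTrack


@pytest.fixture(scope="session")
def nest1():
    return one_chamber_nest()


@pytest.fixture(scope="session")
def nest4():
    return four_chamber_nest()


@pytest.fixture(scope="session")
def small_colony(nest4):
    """30 ants, 3000 s, two well-separated planted groups (fast reusable sim)."""
    from colonystate.synthetic_data import ColonyScenario, simulate_tracks

    scenario = ColonyScenario(n_ants=30, nest=nest4, duration=3000, seed=21)
    tracks = simulate_tracks(scenario)
    labels, homes = scenario.resolve_groups()
    return scenario, tracks, labels, homes


def stationary_track(ant_id: str, point, duration: int) -> AntTrack:
    """Track fixed at one point for every second (test helper)."""
    xy = np.tile(np.asarray(point, dtype=float), (duration + 1, 1))
    return AntTrack(ant_id, xy, np.full(duration + 1, IN_NEST, dtype=np.int8))
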