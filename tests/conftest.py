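import numpy as np
import pytest

from genosdm import EnvGrid, OccurrenceSet


@pytest.fixture
def two_layer_grid():
    """Deterministic 10x10 grid with two gradients and a masked corner."""
    rows = cols = 10
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    mask = np.ones((rows, cols), dtype=bool)
    mask[0, 0] = mask[9, 9] = False
    vals = np.stack([cc / 9.0, rr / 9.0])
    return EnvGrid(["env1", "env2"], vals, mask, origin_x=0.0, origin_y=10.0,
                   cell_size=1.0)


@pytest.fixture
def simple_records():
    return OccurrenceSet.from_arrays(
        x=[1.5, 2.5, 3.5, 4.5], y=[8.5, 7.5, 6.5, 5.5], range_label="test")


@pytest.fixture(scope="session")
def default_scenario():
    """Default synthetic study system, generated once per test session."""
    from genosdm import ScenarioSpec, generate_scenario

    return generate_scenario(ScenarioSpec(seed=0))
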