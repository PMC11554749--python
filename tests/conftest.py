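import numpy as np
import pytest

from afmi.io import SpectralCube, default_channel_table


@pytest.fixture(scope="session")
def channel_table():
    return default_channel_table()


@pytest.fixture
def make_cube(channel_table):
    """Factory for small cubes with an arbitrary processing history."""

    def _make(pixels, stage="raw", history=(), **kw):
        pixels = np.asarray(pixels, dtype=float)
        channels = channel_table[: pixels.shape[2]]
        return SpectralCube(
            pixels=pixels, channels=channels, stage=stage,
            history=tuple(history), field_id=kw.pop("field_id", "F000"), **kw,
        )

    return _make


@pytest.fixture(scope="session")
def status_sim():
    """Default status population (senescence task conditions)."""
    from afmi.synthetic import simulate_cells, status_scenario

    return simulate_cells(status_scenario(seed=11))


@pytest.fixture(scope="session")
def aging_sim_small():
    """Reduced aging population for fast growth-module tests."""
    from afmi.synthetic import aging_scenario, simulate_cells

    sc = aging_scenario(
        seed=12, cells_per_class=30, doubling_classes=tuple(range(0, 24, 2))
    )
    return simulate_cells(sc)
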