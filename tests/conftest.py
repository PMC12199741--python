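"""Shared fixtures: small analytic fields and grids built at test time."""

import numpy as np
import pytest
from hypothesis import settings

import driftsource as ds

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uniform_field():
    """0.1 m/s eastward everywhere, 20°x20° box spanning ±10° latitude."""
    return ds.synth.make_field("uniform", ((0.0, 20.0), (-10.0, 10.0)), 0.5,
                               ("2024-01-01", "2024-03-31"), u0=0.1, v0=0.0)


@pytest.fixture(scope="session")
def gyre_field():
    """Steady two-gyre circulation, |u| ~ 0.3 m/s."""
    return ds.synth.make_field("double_gyre", ((0.0, 20.0), (10.0, 30.0)), 0.5,
                               ("2024-01-01", "2024-06-30"), amplitude=0.3)


@pytest.fixture(scope="session")
def sink_island():
    """(center, radius°) of the designated known-source island."""
    return ((10.0, 20.0), 0.4)


@pytest.fixture(scope="session")
def sink_field(sink_island):
    """Field whose backtracked (time-reversed) flow converges on the island."""
    return ds.synth.make_field("convergent_sink", ((0.0, 20.0), (10.0, 30.0)), 0.5,
                               ("2024-01-01", "2024-04-30"), gamma=2e-6,
                               center=sink_island[0], land_islands=[sink_island])


@pytest.fixture(scope="session")
def sink_settlement(sink_island):
    cells = ds.build_hex_grid((0.0, 20.0), (10.0, 30.0), 1.0)
    return ds.activate_cells(cells, ds.synth.make_coastline([sink_island]))


@pytest.fixture(scope="session")
def unit_grid():
    """1° hex grid over a 10°x10° box, all cells activated."""
    from shapely.geometry import box
    cells = ds.build_hex_grid((0.0, 10.0), (0.0, 10.0), 1.0)
    return ds.activate_cells(cells, [box(-1.0, -1.0, 11.0, 11.0)])
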