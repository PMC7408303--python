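import numpy as np
import pytest

from tabcal.formulation import PAPER_CONSTRAINTS, reference_design
from tabcal.surface import fit_surface
from tabcal.synthetic import (
    LinearTransfer,
    QuadraticTransfer,
    RegionwiseTransfer,
    default_dt_scenario,
    default_ts_scenario,
    generate_api_observations,
    generate_placebo_observations,
)


@pytest.fixture(scope="session")
def design():
    """Labeled ten-run reference design (Rp.2 duplicated)."""
    return reference_design()


@pytest.fixture(scope="session")
def design_map(design):
    return dict(design)  # duplicate Rp.2 collapses; 9 distinct labels


@pytest.fixture(scope="session")
def constraints():
    return PAPER_CONSTRAINTS


@pytest.fixture(scope="session")
def ts_scenario():
    """Zero-noise strength scenario with known affine transfer (0.8, -0.1)."""
    return default_ts_scenario(a=0.8, b=-0.1, noise_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def dt_scenario(design_map):
    """Zero-noise region-wise DT scenario, continuous at the shared anchor.

    The left quadratic and right linear transfers are made to agree at the
    placebo value of Rp.4 (which anchors both fits), so all three left
    anchors lie exactly on the generating quadratic.
    """
    base = default_dt_scenario()
    v4 = base.field(design_map["Rp.4"])
    right = LinearTransfer(0.85, 3.0)
    a, b = 0.004, 0.5
    c = right(v4) - a * v4 * v4 - b * v4
    return default_dt_scenario(
        transfer=RegionwiseTransfer(QuadraticTransfer(a, b, c), right), seed=42
    )


@pytest.fixture(scope="session")
def ts_data(ts_scenario, design):
    placebo = generate_placebo_observations(ts_scenario, design)
    api = generate_api_observations(ts_scenario, design, drug_load=20.0)
    return placebo, api


@pytest.fixture(scope="session")
def ts_surfaces(ts_data):
    placebo, api = ts_data
    return fit_surface(placebo), fit_surface(api)


@pytest.fixture(scope="session")
def dt_data(dt_scenario, design):
    placebo = generate_placebo_observations(dt_scenario, design)
    api = generate_api_observations(dt_scenario, design, drug_load=20.0)
    return placebo, api
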