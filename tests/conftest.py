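"""Shared fixtures.

The simulation-heavy experiment tables are computed once per session in
scaled-down mode (2 µs timestep, 5 µm axonal compartments); individual
tests then make assertions against the shared tables.
"""

import numpy as np
import pytest

from chandelier import (
    SCALED,
    build_canonical_model,
    discretize,
    equilibrium,
    fig1_resistive_coupling,
    fig3_sweeps,
    fig4_position_and_plasticity,
    fig5_kinetics,
)


@pytest.fixture(scope="session")
def canonical_cell():
    return discretize(build_canonical_model(),
                      SCALED.max_seg_axon_um, SCALED.max_seg_dendrite_um)


@pytest.fixture(scope="session")
def resting_state(canonical_cell):
    return equilibrium(canonical_cell)


@pytest.fixture(scope="session")
def fig1_result():
    return fig1_resistive_coupling(SCALED)


@pytest.fixture(scope="session")
def fig3_results():
    return fig3_sweeps(SCALED)


@pytest.fixture(scope="session")
def fig4_results():
    return fig4_position_and_plasticity(SCALED)


@pytest.fixture(scope="session")
def fig5_result():
    return fig5_kinetics(SCALED)


def linfit(x, y):
    """Least-squares slope, intercept and R² (helper for sweep tables)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - np.var(resid) / np.var(y)
    return slope, intercept, r2
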