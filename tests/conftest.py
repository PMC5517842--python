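"""Shared fixtures: baseline parameters and cached reference simulations.

The long free-boundary runs are session-scoped so the acceptance and
property tests share them instead of re-integrating 60 days repeatedly.
"""

import pytest

from melsim import baseline_parameters, simulate, SolverOptions


@pytest.fixture(scope="session")
def params():
    return baseline_parameters()


@pytest.fixture(scope="session")
def coarse_opts():
    """Reduced resolution used for dose sweeps (61 nodes, 0.01-day steps)."""
    return SolverOptions(n_nodes=61, tau=0.01)


@pytest.fixture(scope="session")
def control_coarse(params, coarse_opts):
    """60-day untreated run at reduced resolution."""
    return simulate(params, None, None, 60.0, coarse_opts)


@pytest.fixture(scope="session")
def control_full(params):
    """60-day untreated run at the default resolution (101 nodes, 0.005 day)."""
    return simulate(params, None, None, 60.0, SolverOptions())
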