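"""Shared fixtures: simulated streams at tiny and full scale.

Full-scale fixtures (n = 2000, the benchmark study conditions) are
session-scoped because the Lorenz integration dominates their cost;
every test that needs them shares one simulation and one model fit.
"""

import numpy as np
import pytest

from commonmap.altdiff import AlternatingDiffusionMaps
from commonmap.dynamics import ReactionParams, simulate_reaction
from commonmap.sensing import StreamConfig, make_experiment_streams


@pytest.fixture(scope="session")
def clean_streams():
    """Full-scale clean setup: delay-coordinate channels, one system each."""
    return make_experiment_streams("clean", StreamConfig())


@pytest.fixture(scope="session")
def causal1_streams():
    """Full-scale first causality setup (sensor 2 shifted 200 time units ahead)."""
    return make_experiment_streams("causal1", StreamConfig())


@pytest.fixture(scope="session")
def mixed_streams():
    """Full-scale dirty-channel setup (standardized clean channels, mixed)."""
    return make_experiment_streams("mixed", StreamConfig())


@pytest.fixture(scope="session")
def adm_clean(clean_streams):
    s1, s2, _ = clean_streams
    return AlternatingDiffusionMaps(s1, s2).fit()


@pytest.fixture(scope="session")
def adm_causal1(causal1_streams):
    s1, s2, _ = causal1_streams
    return AlternatingDiffusionMaps(s1, s2).fit()


@pytest.fixture(scope="session")
def adm_mixed(mixed_streams):
    s1, s2, _ = mixed_streams
    return AlternatingDiffusionMaps(s1, s2).fit()


@pytest.fixture(scope="session")
def x_trajectory():
    """Limit-cycle trajectory of the common system, ~24 periods post burn-in."""
    return simulate_reaction(ReactionParams(), t_end=28000.0, dt_out=10.0,
                             burn_in=8000.0)


@pytest.fixture(scope="session")
def circle_points():
    """500 points uniform on the unit circle (analytic eigenfunction testbed)."""
    theta = np.linspace(0.0, 2.0 * np.pi, 500, endpoint=False)
    return theta, np.column_stack([np.cos(theta), np.sin(theta)])
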