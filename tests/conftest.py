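"""Shared fixtures: synthetic forcing at several resolutions and a tuned truth study.

Session-scoped because the annual-resolution forcing and the tuned truth
study are the expensive pieces; everything downstream reuses them.
"""

import numpy as np
import pytest

import greensahara as gs


@pytest.fixture(scope="session")
def default_forcing():
    """Annual-resolution synthetic forcing over 230-0 ka."""
    return gs.make_forcing()


@pytest.fixture(scope="session")
def coarse_forcing():
    """100-yr-resolution synthetic forcing (cheap threshold-time work)."""
    return gs.make_forcing(gs.SyntheticForcingSpec(timestep=100.0))


@pytest.fixture(scope="session")
def truth_study():
    """Truth member tuned to six green episodes in 230-20 ka."""
    return gs.make_truth_study(seed=0)


@pytest.fixture(scope="session")
def screened_ensemble(default_forcing, truth_study):
    """300-member screened + extended ensemble with the truth planted as member 0."""
    return gs.run_pipeline(
        default_forcing,
        300,
        base_seed=truth_study.seed,
        thin=100,
        params_override={0: truth_study.params},
    )


def constant_forcing(P=0.0, F=0.0, n=501, oldest=None, dt=1.0):
    """Helper: flat forcing series of n annual points."""
    oldest = (n - 1) * dt if oldest is None else oldest
    t = oldest - dt * np.arange(n)
    return gs.ForcingSeries(t, np.full(n, float(P)), np.full(n, float(F)))
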