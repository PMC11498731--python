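"""Shared fixtures: one small synthetic scenario reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from tigermove import landscape as ls
from tigermove import simulate, trajectory as tj


@pytest.fixture(scope="session")
def sim_cfg():
    return simulate.SimConfig(seed=11, nrow=120, ncol=120, n_villages=6,
                              n_steps=1500)


@pytest.fixture(scope="session")
def stack(sim_cfg):
    return simulate.make_landscape(sim_cfg)


@pytest.fixture(scope="session")
def land_std(sim_cfg, stack):
    return simulate.landscape_standardizer(stack)


@pytest.fixture(scope="session")
def hmm_steps(sim_cfg, stack, land_std):
    """Steps from one switching-walk track, with covariates and true states."""
    track, states = simulate.simulate_hmm_track(sim_cfg, stack, std=land_std,
                                                boundary="periodic")
    steps = tj.assign_diel(tj.compute_steps(track))
    for c in sim_cfg.covariates:
        steps[c] = track.attrs["step_covariates"][c].to_numpy()
    steps.attrs["states"] = states
    return steps


@pytest.fixture(scope="session")
def ssf_steps(stack, land_std):
    """Steps from one habitat-selecting track over the session landscape."""
    cfg = simulate.SimConfig(seed=12, nrow=120, ncol=120, n_villages=6,
                             n_steps=800)
    track = simulate.simulate_ssf_track(cfg, stack, std=land_std)
    steps = tj.assign_diel(tj.compute_steps(track))
    steps.attrs["cfg"] = cfg
    return steps


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def hourly_track():
    """Small complete hourly track for regularization / step tests."""
    t = pd.date_range("2016-01-01 00:00", periods=6, freq="h")
    return pd.DataFrame({"animal": "a", "time": t,
                         "x": [0.0, 100, 250, 300, 500, 650],
                         "y": [0.0, 0, 50, 200, 180, 300]})
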