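"""Shared fixtures: small reference systems and one physiological run."""

import numpy as np
import pytest

from pelotons.config import get_preset
from pelotons.model import ModelParams
from pelotons.simulate import run


def collect_gaps(traj):
    """All motor-motor gap sizes over the snapshot ensemble."""
    from pelotons.observables import gap_sizes
    out = []
    for s in traj.snapshots:
        out.extend(g for g, _ in gap_sizes(s, traj.params))
    return out


@pytest.fixture(scope="session")
def table1_high_run():
    """Open-gene run at the physiological preset, highest initiation rate
    (3 pol/min): the peloton-forming, bursty regime."""
    cfg = get_preset("table1", k_in="3/min")
    return run(cfg.params, t_max=8000.0, dt_sample=1.0, burn_in=2000.0,
               seed=11)


@pytest.fixture(scope="session")
def brm_mid_run():
    """Bus-Route ring at intermediate roadblock density (k_ip * tau = 10,
    motor density 0.1): the double-geometric gap regime."""
    params = ModelParams(L=1000, delta_m=1, delta_rb=1, k_ip=1.0, k_tp=0.3,
                         k_b=0.1, boundary="periodic", n_motors=100)
    return run(params, t_max=4000.0, dt_sample=10.0, burn_in=2000.0, seed=9)
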