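"""Exact continuous-time Markov chain solver for tiny Bus-Route systems.

For unit-footprint motors and roadblocks on a small ring the full state
space is enumerable: a configuration is a set of motor sites plus a set
of roadblock sites on the remaining lattice.  This module builds the
generator of that chain directly from the Bus-Route Model rules --
written down independently of :mod:`pelotons.model`, so it can serve as
an oracle for the simulator -- and solves for the stationary
distribution.  It also converts a simulated trajectory into the
time-weighted empirical distribution over configurations for direct
total-variation comparison.

Only ``delta_m = delta_rb = 1``, periodic, uniform-interaction systems
are supported; the state space grows as ``C(L, n) * 2**(L - n)``.
"""

from __future__ import annotations

from itertools import combinations, chain

import numpy as np
from scipy import linalg

from .simulate import BIND, STEP, Trajectory

__all__ = ["enumerate_states", "brm_stationary", "empirical_distribution",
           "total_variation"]

State = tuple[tuple[int, ...], tuple[int, ...]]  # (motor sites, roadblock sites)


def _subsets(items: tuple[int, ...]):
    return chain.from_iterable(combinations(items, r)
                               for r in range(len(items) + 1))


def enumerate_states(L: int, n_motors: int) -> list[State]:
    """All configurations of ``n_motors`` unit motors and any number of
    unit roadblocks on a ring of ``L`` sites."""
    states: list[State] = []
    for motors in combinations(range(L), n_motors):
        free = tuple(s for s in range(L) if s not in motors)
        for rbs in _subsets(free):
            states.append((motors, rbs))
    return states


def brm_stationary(
    L: int, n_motors: int, k_ip: float, k_tp: float, k_b: float
) -> dict[State, float]:
    """Stationary distribution of the Bus-Route Model on a small ring.

    Rules, hand-coded: a motor at ``i`` hops to ``(i+1) % L`` when no
    motor is there, at rate ``k_tp`` if a roadblock occupies the target
    (which is then removed) and ``k_ip`` otherwise; a roadblock binds at
    rate ``k_b`` on every site free of motors and roadblocks.
    """
    states = enumerate_states(L, n_motors)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for s, i in index.items():
        motors, rbs = s
        mset, rset = set(motors), set(rbs)
        for m in motors:
            tgt = (m + 1) % L
            if tgt in mset:
                continue
            rate = k_tp if tgt in rset else k_ip
            new_m = tuple(sorted(mset - {m} | {tgt}))
            new_r = tuple(sorted(rset - {tgt}))
            j = index[(new_m, new_r)]
            Q[i, j] += rate
            Q[i, i] -= rate
        if k_b > 0:
            for site in range(L):
                if site in mset or site in rset:
                    continue
                new_r = tuple(sorted(rset | {site}))
                j = index[(motors, new_r)]
                Q[i, j] += k_b
                Q[i, i] -= k_b
    # stationary vector: left null space of Q (pi Q = 0, pi 1 = 1)
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = linalg.lstsq(A, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return {s: float(pi[index[s]]) for s in states}


def empirical_distribution(
    trajectory: Trajectory, burn_in: float | None = None
) -> dict[State, float]:
    """Time-weighted occupancy of configurations along a simulated
    Bus-Route trajectory (unit footprints, periodic).

    The event log is replayed from the initial state; each
    configuration's weight is the total time spent in it after
    ``burn_in``, normalized to 1.
    """
    params = trajectory.params
    if params.delta_m != 1 or params.delta_rb != 1 or not params.periodic \
            or params.interaction != "uniform":
        raise ValueError("empirical_distribution expects a unit-footprint "
                         "periodic uniform-mode trajectory")
    L = params.L
    if burn_in is None:
        burn_in = trajectory.burn_in
    mset = set(trajectory.initial_state.motors)
    rset = set(trajectory.initial_state.roadblocks)
    weights: dict[State, float] = {}
    t_prev = 0.0

    def key() -> State:
        return (tuple(sorted(mset)), tuple(sorted(rset)))

    k = key()
    for t, kind, pos in zip(trajectory.times.tolist(),
                            trajectory.kinds.tolist(),
                            trajectory.positions.tolist()):
        if t > burn_in:
            lo = max(t_prev, burn_in)
            weights[k] = weights.get(k, 0.0) + (t - lo)
        if kind == STEP:
            prev = (pos - 1) % L
            mset.discard(prev)
            mset.add(pos)
            rset.discard(pos)  # arrival removes any roadblock there
        elif kind == BIND:
            rset.add(pos)
        k = key()
        t_prev = t
    if trajectory.t_max > max(t_prev, burn_in):
        weights[k] = weights.get(k, 0.0) + trajectory.t_max - max(t_prev, burn_in)
    total = sum(weights.values())
    return {s: w / total for s, w in weights.items()}


def total_variation(p: dict[State, float], q: dict[State, float]) -> float:
    """Total-variation distance between two distributions over states."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
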