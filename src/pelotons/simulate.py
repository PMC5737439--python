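"""Exact kinetic Monte Carlo engine for the motor-roadblock lattice gas.

The engine draws exponentially distributed waiting times over the full
event catalogue (Gillespie's direct method) and keeps per-motor rates up
to date with local neighbourhood updates, which is equivalent in law to
recomputing the whole catalogue after every event.  Roadblock binding is
sampled by thinning: attempts occur at the constant total rate
``k_b * n_positions`` over *all* leftmost positions and attempts at
inadmissible positions are discarded, which realizes independent binding
at rate ``k_b`` per admissible position exactly.

Realized events are logged (``step``, ``initiate``, ``terminate``,
``bind``); evictions are implied by the step that triggers them, so event
times are strictly increasing.  Snapshots of the full configuration are
recorded on a fixed grid after an initial burn-in and are the canonical
source for the statistics in :mod:`pelotons.observables`.
"""

from __future__ import annotations

import math
from array import array
from dataclasses import dataclass, field

import numpy as np

from .model import LatticeState, ModelParams

__all__ = ["Trajectory", "Kymograph", "run", "to_kymograph",
           "STEP", "INITIATE", "TERMINATE", "BIND", "KIND_NAMES",
           "EMPTY", "MOTOR", "ROADBLOCK"]

# event codes in Trajectory.kinds
STEP, INITIATE, TERMINATE, BIND = 0, 1, 2, 3
KIND_NAMES = {STEP: "step", INITIATE: "initiate", TERMINATE: "terminate",
              BIND: "bind_roadblock"}

# occupancy codes in Kymograph.matrix
EMPTY, MOTOR, ROADBLOCK = 0, 1, 2


@dataclass
class Trajectory:
    """Time-stamped event log plus sampled configurations.

    ``times``/``kinds``/``positions`` are parallel arrays over realized
    events (position is the *new* leftmost site for steps, the leftmost
    site for initiations/bindings, and the final leftmost site for
    terminations).  ``snapshots`` are :class:`LatticeState` samples every
    ``dt_sample`` seconds starting at ``burn_in``.
    """

    params: ModelParams
    t_max: float
    burn_in: float
    dt_sample: float
    seed: int | None
    times: np.ndarray
    kinds: np.ndarray
    positions: np.ndarray
    snapshots: list[LatticeState]
    initial_state: LatticeState

    @property
    def termination_times(self) -> np.ndarray:
        return self.times[self.kinds == TERMINATE]

    @property
    def initiation_times(self) -> np.ndarray:
        return self.times[self.kinds == INITIATE]

    def n_events(self) -> int:
        return len(self.times)


@dataclass
class Kymograph:
    """Position-vs-time raster of lattice occupancy.

    ``matrix[b, x]`` holds one of ``EMPTY``/``MOTOR``/``ROADBLOCK`` for
    time bin ``b`` and lattice site ``x``; motors take precedence over
    roadblocks on shared sites (dyad-mode traversal).
    """

    matrix: np.ndarray
    t0: float
    dt_bin: float

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def _default_initial(params: ModelParams) -> LatticeState:
    if params.periodic:
        n = params.n_motors
        if n > 0 and params.L // n < params.delta_m:
            raise ValueError("cannot place n_motors without overlap")
        motors = tuple(i * (params.L // n) for i in range(n)) if n else ()
        return LatticeState(time=0.0, motors=motors, roadblocks=())
    return LatticeState(time=0.0, motors=(), roadblocks=())


def run(
    params: ModelParams,
    t_max: float,
    dt_sample: float = 1.0,
    burn_in: float = 0.0,
    seed: int | None = None,
    initial_state: LatticeState | None = None,
) -> Trajectory:
    """Simulate the lattice gas exactly from ``t = 0`` to ``t_max``.

    Parameters
    ----------
    params
        Model parameters (rates, footprints, boundary mode).
    t_max, dt_sample, burn_in
        Total simulated time, snapshot interval, and the time before the
        first snapshot, all in seconds.
    seed
        RNG seed; falls back to ``params.seed``, then 0.  Identical seeds
        give identical event logs.
    initial_state
        Optional starting configuration; defaults to an empty open
        lattice or evenly spaced motors on a ring.
    """
    if not t_max > burn_in >= 0:
        raise ValueError("need t_max > burn_in >= 0")
    if dt_sample <= 0:
        raise ValueError("dt_sample must be positive")
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    rng = np.random.default_rng(seed)
    rnd = rng.random

    L, dm, drb = params.L, params.delta_m, params.delta_rb
    k_ip, k_tp, k_in, k_b = params.k_ip, params.k_tp, params.k_in, params.k_b
    per = params.periodic
    dyad_mode = params.interaction == "dyad"
    off = params.dyad_offset
    tail_slow = drb - 1 - off  # slow steps remaining after dyad eviction

    state0 = initial_state if initial_state is not None else _default_initial(params)
    from .model import validate_state
    validate_state(state0, params)

    mocc = bytearray(L)
    rocc = bytearray(L)
    rleft = [-1] * L  # site -> leftmost site of the intact roadblock covering it
    motors: list[int] = list(state0.motors)
    slowl: list[int] = list(state0.slow_left)
    for p in motors:
        for k in range(dm):
            mocc[(p + k) % L if per else p + k] = 1
    rset: set[int] = set(state0.roadblocks)
    for q in state0.roadblocks:
        for k in range(drb):
            s = (q + k) % L if per else q + k
            rocc[s] = 1
            rleft[s] = q

    def calc_rate(i: int) -> float:
        p = motors[i]
        f = (p + dm - 1) % L if per else p + dm - 1
        if not per and f == L - 1:
            return k_ip
        tgt = (f + 1) % L if per else f + 1
        if mocc[tgt]:
            return 0.0
        if dyad_mode and slowl[i] > 0:
            return k_tp
        if rocc[tgt]:
            return k_tp
        return k_ip

    rates: list[float] = [calc_rate(i) for i in range(len(motors))]
    tot_m = sum(rates)

    n_pos = L if per else L - drb + 1
    R_bind = k_b * n_pos

    times = array("d")
    kinds = array("b")
    poss = array("l")
    snapshots: list[LatticeState] = []

    def snap(at: float) -> None:
        snapshots.append(LatticeState(
            time=at,
            motors=tuple(motors),
            roadblocks=tuple(sorted(rset)),
            slow_left=tuple(slowl),
        ))

    t = 0.0
    next_s = burn_in
    n_ev = 0
    log = math.log

    while True:
        init_ok = (not per) and k_in > 0 and mocc.find(1, 0, dm) == -1
        R = R_bind + tot_m + (k_in if init_ok else 0.0)
        if R <= 0.0:
            t = t_max
            break
        t += -log(1.0 - rnd()) / R
        if t >= t_max:
            break
        while next_s <= t and next_s < t_max:
            snap(next_s)
            next_s += dt_sample

        u = rnd() * R
        if u < R_bind:
            # binding attempt at a uniformly chosen leftmost position
            q = int(rnd() * n_pos)
            if q >= n_pos:  # guard against rnd() == 1.0 edge
                q = n_pos - 1
            if not per and q < dm:
                continue  # promoter is kept roadblock-free
            if per and q + drb > L:
                free = (mocc.find(1, q, L) == -1 and rocc.find(1, q, L) == -1
                        and mocc.find(1, 0, q + drb - L) == -1
                        and rocc.find(1, 0, q + drb - L) == -1)
            else:
                free = (mocc.find(1, q, q + drb) == -1
                        and rocc.find(1, q, q + drb) == -1)
            if not free:
                continue
            rset.add(q)
            for k in range(drb):
                s = (q + k) % L if per else q + k
                rocc[s] = 1
                rleft[s] = q
            # the motor immediately behind the new roadblock may slow down
            b = (q - 1) % L if per else q - 1
            if b >= 0 and mocc[b] and (per or not mocc[q % L if per else q]):
                for j, p in enumerate(motors):
                    if ((p + dm - 1) % L if per else p + dm - 1) == b:
                        new = calc_rate(j)
                        tot_m += new - rates[j]
                        rates[j] = new
                        break
            times.append(t)
            kinds.append(BIND)
            poss.append(q)
        elif init_ok and u < R_bind + k_in:
            motors.insert(0, 0)
            slowl.insert(0, 0)
            for k in range(dm):
                mocc[k] = 1
            rates.insert(0, 0.0)
            new = calc_rate(0)
            tot_m += new
            rates[0] = new
            times.append(t)
            kinds.append(INITIATE)
            poss.append(0)
        else:
            # motor step: linear scan over per-motor rates
            v = u - R_bind - (k_in if init_ok else 0.0)
            i = 0
            nm = len(motors)
            acc = 0.0
            for i in range(nm):
                acc += rates[i]
                if v < acc:
                    break
            p = motors[i]
            f = (p + dm - 1) % L if per else p + dm - 1
            if not per and f == L - 1:
                # exit: remove the whole motor
                for k in range(dm):
                    mocc[p + k] = 0
                tot_m -= rates[i]
                del motors[i], slowl[i], rates[i]
                times.append(t)
                kinds.append(TERMINATE)
                poss.append(p)
                if motors:
                    j = len(motors) - 1  # new leading motor may unblock
                    new = calc_rate(j)
                    tot_m += new - rates[j]
                    rates[j] = new
                continue
            tgt = (f + 1) % L if per else f + 1
            if dyad_mode and slowl[i] > 0:
                slowl[i] -= 1
            if rocc[tgt]:
                q = rleft[tgt]
                if dyad_mode:
                    dy = (q + off) % L if per else q + off
                    evict = tgt == dy
                    if evict:
                        slowl[i] = tail_slow
                else:
                    evict = True
                if evict:
                    rset.discard(q)
                    for k in range(drb):
                        s = (q + k) % L if per else q + k
                        rocc[s] = 0
                        rleft[s] = -1
            mocc[p] = 0
            mocc[tgt] = 1
            motors[i] = (p + 1) % L if per else p + 1
            new = calc_rate(i)
            tot_m += new - rates[i]
            rates[i] = new
            # the motor behind may have been unblocked by the vacated site
            nm = len(motors)
            if nm > 1:
                j = (i - 1) % nm if per else i - 1
                if j >= 0:
                    new = calc_rate(j)
                    tot_m += new - rates[j]
                    rates[j] = new
            times.append(t)
            kinds.append(STEP)
            poss.append(motors[i])

        n_ev += 1
        if n_ev & 0xFFFF == 0:
            tot_m = sum(rates)  # kill floating-point drift

    while next_s < t_max - 1e-12:
        snap(next_s)
        next_s += dt_sample

    return Trajectory(
        params=params,
        t_max=t_max,
        burn_in=burn_in,
        dt_sample=dt_sample,
        seed=seed,
        times=np.frombuffer(times, dtype=np.float64).copy()
        if times else np.empty(0),
        kinds=np.array(kinds, dtype=np.int8),
        positions=np.array(poss, dtype=np.int64),
        snapshots=snapshots,
        initial_state=state0,
    )


def to_kymograph(
    trajectory: Trajectory, t0: float, t1: float, dt_bin: float
) -> Kymograph:
    """Rasterize snapshots in ``[t0, t1)`` into an occupancy matrix.

    Each time bin is represented by the first snapshot falling in it
    (bins without a snapshot stay empty); motors overwrite roadblocks on
    shared sites.
    """
    if not (t0 < t1):
        raise ValueError("need t0 < t1")
    lo = trajectory.burn_in
    if t0 < lo - 1e-9 or t1 > trajectory.t_max + 1e-9:
        raise ValueError("kymograph range outside the sampled trajectory span")
    if dt_bin <= 0:
        raise ValueError("dt_bin must be positive")
    params = trajectory.params
    L, dm, drb = params.L, params.delta_m, params.delta_rb
    per = params.periodic
    n_bins = int(math.ceil((t1 - t0) / dt_bin))
    mat = np.zeros((n_bins, L), dtype=np.int8)
    filled = np.zeros(n_bins, dtype=bool)
    for s in trajectory.snapshots:
        if not (t0 <= s.time < t1):
            continue
        b = int((s.time - t0) / dt_bin)
        if b >= n_bins or filled[b]:
            continue
        filled[b] = True
        row = mat[b]
        for q in s.roadblocks:
            for k in range(drb):
                row[(q + k) % L if per else q + k] = ROADBLOCK
        for p in s.motors:
            for k in range(dm):
                row[(p + k) % L if per else p + k] = MOTOR
    return Kymograph(matrix=mat, t0=t0, dt_bin=dt_bin)
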