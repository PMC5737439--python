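"""State space and rate rules of the motor-roadblock lattice gas.

The model describes molecular motors (RNA polymerase II) translocating
unidirectionally along a one-dimensional lattice (DNA, one site = 1 bp)
covered by dynamically rebinding roadblocks (nucleosomes).  The bulk rules
are:

1. motors hop one site at a time in the +x direction,
2. motors exclude each other sterically and cannot overtake,
3. roadblocks bind on stretches of the lattice that can accommodate their
   full footprint,
4. a roadblock ahead of a motor slows the motor from the bare-DNA rate
   ``k_ip`` to the through-roadblock rate ``k_tp``,
5. a passing motor displaces the roadblock; the roadblock can only return
   through a fresh binding event.

Two interaction variants are provided.  In ``uniform`` mode a motor can
never overlap a roadblock: the step onto the roadblock's first footprint
site is slow and displaces it (for footprint 1 this is exactly the
Bus-Route Model).  In ``dyad`` mode -- the transcription scenario -- the
motor transcribes *through* the nucleosome: every step whose target site
lies within an intact roadblock footprint proceeds at ``k_tp``, the histone
complex is displaced when the motor front passes the central (dyad) site,
and the motor keeps the slow rate for the remainder of the former
footprint (it is still threading through the displaced histones).  The net
effect is exactly ``delta_rb`` slow steps per nucleosome, i.e. a
through-nucleosome velocity of ``k_tp``, which is what anchors the
effective rebinding time ``tau_Delta = tau + delta_rb/k_tp`` of the
analytic theory (:mod:`pelotons.theory`).

This module holds only the *rules*: pure functions from states to rates
and successor states.  Time evolution lives in :mod:`pelotons.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

__all__ = [
    "ModelParams",
    "LatticeState",
    "Event",
    "motor_step_rate",
    "apply_step",
    "roadblock_binding_positions",
    "initiation_rate",
    "enumerate_events",
    "validate_state",
]


@dataclass(frozen=True)
class ModelParams:
    """Microscopic rates, footprints, and lattice configuration.

    Parameters
    ----------
    L
        Lattice length in sites (1 site = 1 bp).
    delta_m
        Motor footprint in sites (RNAP covers ~35 bp).
    delta_rb
        Roadblock footprint in sites (nucleosome + linker, ~167 bp).
    k_ip
        Intra-peloton (bare-track) hopping rate, 1/s.  Equals the motor
        velocity in bp/s on an empty track.
    k_tp
        Trans-peloton (through-roadblock) hopping rate, 1/s.
    k_in
        Initiation rate at the open boundary, 1/s.
    k_b
        Roadblock binding-attempt rate per admissible position, 1/s.
        ``k_b = 0`` disables roadblocks entirely (pure TASEP limit).
    tau
        Roadblock equilibration time in s, used by the analytic layer.
        ``None`` means "derive from the binding process" (``1/k_b``).
        The physiological preset sets ``tau = 0`` because histone
        rebinding is fast compared to clearing the footprint.
    boundary
        ``"open"`` (initiation at site 0, termination past site L-1) or
        ``"periodic"`` (ring with a conserved number of motors).
    interaction
        ``"uniform"`` or ``"dyad"`` (see module docstring).
    n_motors
        Motor count for periodic mode (ignored for open boundaries).
    seed
        Default RNG seed for simulations of this parameter set.
    """

    L: int
    delta_m: int = 1
    delta_rb: int = 1
    k_ip: float = 1.0
    k_tp: float = 1.0
    k_in: float = 0.0
    k_b: float = 0.0
    tau: float | None = None
    boundary: str = "open"
    interaction: str = "uniform"
    n_motors: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.delta_m < 1:
            raise ValueError(f"delta_m must be >= 1, got {self.delta_m}")
        if self.delta_rb < 1:
            raise ValueError(f"delta_rb must be >= 1, got {self.delta_rb}")
        if self.L <= self.delta_m + self.delta_rb:
            raise ValueError(
                f"L must exceed delta_m + delta_rb = "
                f"{self.delta_m + self.delta_rb}, got L={self.L}"
            )
        if not (0.0 < self.k_tp <= self.k_ip):
            raise ValueError(
                f"need 0 < k_tp <= k_ip, got k_tp={self.k_tp}, k_ip={self.k_ip}"
            )
        if self.k_in < 0:
            raise ValueError(f"k_in must be >= 0, got {self.k_in}")
        if self.k_b < 0:
            raise ValueError(f"k_b must be >= 0, got {self.k_b}")
        if self.tau is not None and self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.boundary not in ("open", "periodic"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")
        if self.interaction not in ("uniform", "dyad"):
            raise ValueError(f"unknown interaction mode {self.interaction!r}")
        if self.boundary == "periodic":
            if self.n_motors < 0:
                raise ValueError("n_motors must be >= 0")
            if self.n_motors * self.delta_m > self.L:
                raise ValueError("n_motors * delta_m exceeds lattice length")

    @property
    def tau_eff(self) -> float:
        """Equilibration time used by the analytic layer (s)."""
        if self.tau is not None:
            return self.tau
        return 1.0 / self.k_b if self.k_b > 0 else math.inf

    @property
    def dyad_offset(self) -> int:
        """Offset of the dyad from the roadblock's leftmost site."""
        return self.delta_rb // 2

    @property
    def periodic(self) -> bool:
        return self.boundary == "periodic"


@dataclass(frozen=True)
class LatticeState:
    """Instantaneous configuration of motors and roadblocks.

    ``motors`` and ``roadblocks`` hold leftmost occupied sites (0-based);
    a motor covers ``[p, p + delta_m - 1]``, a roadblock
    ``[q, q + delta_rb - 1]`` (wrapping on a ring).  Motors are listed in
    ascending order on open lattices and in ring order on periodic ones;
    the order never changes because motors cannot overtake.

    ``slow_left`` is per-motor traversal memory used only in dyad mode:
    the number of remaining slow steps through a displaced roadblock's
    former footprint.  It is zero for motors not currently threading
    through displaced histones.
    """

    time: float
    motors: tuple[int, ...]
    roadblocks: tuple[int, ...]
    slow_left: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.slow_left) != len(self.motors):
            if self.slow_left:
                raise ValueError("slow_left length must match motors")
            object.__setattr__(self, "slow_left", (0,) * len(self.motors))


def _sites(p: int, size: int, L: int, periodic: bool) -> Iterator[int]:
    """Sites covered by a footprint of ``size`` with leftmost site ``p``."""
    for k in range(size):
        s = p + k
        yield s % L if periodic else s


def _covered(positions: tuple[int, ...], size: int, L: int, periodic: bool) -> set[int]:
    out: set[int] = set()
    for p in positions:
        out.update(_sites(p, size, L, periodic))
    return out


def validate_state(state: LatticeState, params: ModelParams) -> None:
    """Raise ``ValueError`` if the state violates a model invariant."""
    L, dm, drb = params.L, params.delta_m, params.delta_rb
    per = params.periodic
    msites: set[int] = set()
    for p in state.motors:
        cov = set(_sites(p, dm, L, per))
        if not per and (p < 0 or p + dm - 1 > L - 1):
            raise ValueError(f"motor at {p} extends outside the lattice")
        if msites & cov:
            raise ValueError("overlapping motors")
        msites |= cov
    rsites: set[int] = set()
    for q in state.roadblocks:
        cov = set(_sites(q, drb, L, per))
        if not per and (q < 0 or q + drb - 1 > L - 1):
            raise ValueError(f"roadblock at {q} extends outside the lattice")
        if rsites & cov:
            raise ValueError("overlapping roadblocks")
        rsites |= cov
        if not per and q < dm:
            raise ValueError("roadblock overlaps the initiation footprint")
    if params.interaction == "uniform":
        if msites & rsites:
            raise ValueError("motor overlaps a roadblock in uniform mode")
    else:
        dyads = {(q + params.dyad_offset) % L if per else q + params.dyad_offset
                 for q in state.roadblocks}
        if msites & dyads:
            raise ValueError("motor occupies an intact dyad in dyad mode")
    if not per and list(state.motors) != sorted(state.motors):
        raise ValueError("motors must be sorted ascending on an open lattice")


def motor_step_rate(
    state: LatticeState, motor_index: int, params: ModelParams
) -> float | None:
    """Rate for motor ``motor_index`` to advance one site, or ``None`` if
    it is sterically blocked by the motor ahead.

    The rate is ``k_tp`` when the newly occupied front site interacts with
    a roadblock (uniform mode: any intact footprint site; dyad mode: any
    intact footprint site, or any site of a footprint the motor is still
    traversing after displacing it), else ``k_ip``.  The last step off an
    open lattice is always unhindered.
    """
    if not 0 <= motor_index < len(state.motors):
        raise IndexError(f"no motor with index {motor_index}")
    L, dm = params.L, params.delta_m
    per = params.periodic
    p = state.motors[motor_index]
    front = (p + dm - 1) % L if per else p + dm - 1
    if not per and front == L - 1:
        return params.k_ip  # exit step off the lattice
    target = (front + 1) % L if per else front + 1
    if target in _covered(tuple(m for i, m in enumerate(state.motors)
                                if i != motor_index), dm, L, per):
        return None
    rb_sites = _covered(state.roadblocks, params.delta_rb, L, per)
    if params.interaction == "uniform":
        return params.k_tp if target in rb_sites else params.k_ip
    if state.slow_left[motor_index] > 0:
        return params.k_tp
    return params.k_tp if target in rb_sites else params.k_ip


def apply_step(
    state: LatticeState, motor_index: int, params: ModelParams
) -> LatticeState:
    """Advance motor ``motor_index`` by one site and apply eviction rules.

    Uniform mode evicts a roadblock as soon as the motor front contacts
    its footprint; dyad mode evicts when the front covers the dyad and
    charges the motor the remaining slow steps through the former
    footprint.  On an open lattice a motor whose front is at the last
    site leaves the lattice entirely.
    """
    rate = motor_step_rate(state, motor_index, params)
    if rate is None:
        raise ValueError(f"motor {motor_index} is blocked and cannot step")
    L, dm, drb = params.L, params.delta_m, params.delta_rb
    per = params.periodic
    motors = list(state.motors)
    slow = list(state.slow_left)
    p = motors[motor_index]
    front = (p + dm - 1) % L if per else p + dm - 1

    if not per and front == L - 1:  # termination
        del motors[motor_index]
        del slow[motor_index]
        return replace(state, motors=tuple(motors), slow_left=tuple(slow))

    target = (front + 1) % L if per else front + 1
    roadblocks = list(state.roadblocks)
    if slow[motor_index] > 0:
        slow[motor_index] -= 1
    hit = None
    for q in roadblocks:
        if target in set(_sites(q, drb, L, per)):
            hit = q
            break
    if hit is not None:
        if params.interaction == "uniform":
            roadblocks.remove(hit)
        else:
            dyad = (hit + params.dyad_offset) % L if per else hit + params.dyad_offset
            if target == dyad:
                roadblocks.remove(hit)
                # remaining footprint sites past the dyad stay slow
                slow[motor_index] = drb - 1 - params.dyad_offset
    motors[motor_index] = (p + 1) % L if per else p + 1
    return replace(
        state,
        motors=tuple(motors),
        roadblocks=tuple(sorted(roadblocks)),
        slow_left=tuple(slow),
    )


def roadblock_binding_positions(
    state: LatticeState, params: ModelParams
) -> set[int]:
    """Admissible leftmost positions for a roadblock binding attempt.

    A position is admissible when the full footprint is free of motors
    and of other roadblocks; on open lattices the footprint must also
    stay clear of the initiation footprint ``[0, delta_m - 1]`` (the
    promoter is kept nucleosome-free) and inside the lattice.
    """
    L, dm, drb = params.L, params.delta_m, params.delta_rb
    per = params.periodic
    msites = _covered(state.motors, dm, L, per)
    rsites = _covered(state.roadblocks, drb, L, per)
    blocked = msites | rsites
    out: set[int] = set()
    candidates = range(L) if per else range(dm, L - drb + 1)
    for q in candidates:
        if all(s not in blocked for s in _sites(q, drb, L, per)):
            out.add(q)
    return out


def initiation_rate(state: LatticeState, params: ModelParams) -> float | None:
    """``k_in`` if the initiation footprint is free of motors, else ``None``.

    Only defined for open boundaries (periodic rings conserve motors).
    """
    if params.periodic:
        raise ValueError("initiation is undefined in periodic mode")
    occupied = _covered(state.motors, params.delta_m, params.L, False)
    if any(s in occupied for s in range(params.delta_m)):
        return None
    return params.k_in


@dataclass(frozen=True)
class Event:
    """One enabled transition of the lattice gas.

    ``kind`` is one of ``step``, ``initiate``, ``terminate``,
    ``bind_roadblock``; ``index`` is the motor index for steps,
    ``position`` the leftmost site for binding events.
    """

    kind: str
    rate: float
    index: int | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("event rate must be positive")


def enumerate_events(state: LatticeState, params: ModelParams) -> list[Event]:
    """The complete catalogue of enabled events with their rates.

    Deterministic given the state; used as the reference law the
    optimized simulator must reproduce, and for comparison with
    independently coded small-system oracles.
    """
    events: list[Event] = []
    L, dm = params.L, params.delta_m
    for i, p in enumerate(state.motors):
        rate = motor_step_rate(state, i, params)
        if rate is None:
            continue
        kind = "step"
        if not params.periodic and p + dm - 1 == L - 1:
            kind = "terminate"
        events.append(Event(kind=kind, rate=rate, index=i))
    if not params.periodic and params.k_in > 0:
        r = initiation_rate(state, params)
        if r:
            events.append(Event(kind="initiate", rate=r))
    if params.k_b > 0:
        for q in sorted(roadblock_binding_positions(state, params)):
            events.append(Event(kind="bind_roadblock", rate=params.k_b, position=q))
    return events
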