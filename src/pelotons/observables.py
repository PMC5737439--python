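"""Statistics extracted from simulated trajectories.

Everything here consumes a :class:`~pelotons.simulate.Trajectory` (or a
single :class:`~pelotons.model.LatticeState`) and produces the
observables the theory predicts: gap-size distributions and their
geometric (mixture) fits, peloton partitions, position-resolved density
and velocity profiles with exponential-relaxation fits, and windowed
burst statistics of the termination stream.

Conventions: the gap between consecutive motors is the number of empty
sites strictly between the front of the trailing motor and the left edge
of the leading one.  A gap is *intra-peloton* when no intact roadblock
interferes with it (uniform mode: no footprint overlap; dyad mode: no
dyad inside it) and *trans-peloton* otherwise; a peloton is a maximal
run of motors connected by intra-peloton gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import LatticeState, ModelParams
from .simulate import INITIATE, STEP, TERMINATE, Trajectory

__all__ = [
    "gap_sizes",
    "GapDistribution",
    "fit_gap_distribution",
    "identify_pelotons",
    "PelotonStats",
    "peloton_stats",
    "ProfileEstimate",
    "estimate_profiles",
    "RelaxationFit",
    "fit_relaxation",
    "BurstSeries",
    "burst_statistics",
]


# ---------------------------------------------------------------------------
# gaps and pelotons


def gap_sizes(
    state: LatticeState, params: ModelParams
) -> list[tuple[int, bool]]:
    """Gaps between consecutive motors with their classification.

    Returns ``(size, is_trans)`` pairs ordered along the track;
    ``is_trans`` is True when an intact roadblock sits in the gap.  On a
    ring every motor contributes its forward gap (cyclic); on an open
    lattice a state with ``n`` motors yields ``n - 1`` gaps.
    """
    L, dm, drb = params.L, params.delta_m, params.delta_rb
    per = params.periodic
    motors = sorted(state.motors) if per else list(state.motors)
    n = len(motors)
    out: list[tuple[int, bool]] = []
    if n == 0 or (n == 1 and not per):
        return out

    if params.interaction == "dyad":
        marks = sorted((q + params.dyad_offset) % L if per
                       else q + params.dyad_offset
                       for q in state.roadblocks)
    else:
        marks = sorted(s for q in state.roadblocks
                       for s in ((q + k) % L if per else q + k
                                 for k in range(drb)))
    marks_arr = np.asarray(marks, dtype=int)

    def occupied_between(a: int, b: int) -> bool:
        """Any interaction mark strictly inside the forward arc (a, b)?"""
        if not per:
            i = np.searchsorted(marks_arr, a, side="right")
            return i < len(marks_arr) and marks_arr[i] < b
        if a < b:
            i = np.searchsorted(marks_arr, a, side="right")
            return i < len(marks_arr) and marks_arr[i] < b
        # arc wraps the origin
        i = np.searchsorted(marks_arr, a, side="right")
        if i < len(marks_arr):
            return True
        return len(marks_arr) > 0 and marks_arr[0] < b

    pairs = zip(motors, motors[1:] + ([motors[0]] if per else []))
    for p_trail, p_lead in pairs:
        front = (p_trail + dm - 1) % L if per else p_trail + dm - 1
        gap = (p_lead - front - 1) % L if per else p_lead - front - 1
        out.append((gap, bool(occupied_between(front, p_lead if not per
                                               else p_lead % L))))
    return out


def identify_pelotons(
    state: LatticeState, params: ModelParams
) -> list[list[int]]:
    """Partition motors into pelotons (maximal runs without interspersed
    roadblocks); returns groups of motor indices into ``state.motors``
    ordered along the track."""
    n = len(state.motors)
    if n == 0:
        return []
    gaps = gap_sizes(state, params)
    order = np.argsort(state.motors) if params.periodic else np.arange(n)
    groups: list[list[int]] = [[int(order[0])]]
    for j in range(n - 1):
        if gaps[j][1]:
            groups.append([int(order[j + 1])])
        else:
            groups[-1].append(int(order[j + 1]))
    if params.periodic and len(groups) > 1 and not gaps[-1][1]:
        groups[0] = groups.pop() + groups[0]  # wrap-around peloton
    return groups


@dataclass
class PelotonStats:
    """Peloton sizes aggregated over snapshots."""

    sizes: np.ndarray          # one entry per peloton observation
    per_snapshot: list[np.ndarray]
    mean_size: float
    spacing: np.ndarray        # trans-peloton gap sizes (sites)


def peloton_stats(
    trajectory: Trajectory,
    t0: float | None = None,
    t1: float | None = None,
    x_window: tuple[int, int] | None = None,
) -> PelotonStats:
    """Aggregate peloton sizes (and trans-peloton spacings) over all
    snapshots in ``[t0, t1)``.

    ``x_window = (a, b)`` keeps only pelotons whose leading-motor front
    lies in ``[a, b)`` — e.g. a window near the end of the gene measures
    the size pelotons have reached when they terminate, without the
    truncation bias of pelotons mid-exit.
    """
    params = trajectory.params
    t0 = trajectory.burn_in if t0 is None else t0
    t1 = trajectory.t_max if t1 is None else t1
    dm, L, per = params.delta_m, params.L, params.periodic
    all_sizes: list[int] = []
    per_snap: list[np.ndarray] = []
    spacing: list[int] = []
    for s in trajectory.snapshots:
        if not (t0 <= s.time < t1):
            continue
        groups = identify_pelotons(s, params)
        sizes = []
        for g in groups:
            if x_window is not None:
                lead = max(g, key=lambda i: s.motors[i]) if not per else g[-1]
                front = (s.motors[lead] + dm - 1) % L if per \
                    else s.motors[lead] + dm - 1
                if not (x_window[0] <= front < x_window[1]):
                    continue
            sizes.append(len(g))
        per_snap.append(np.asarray(sizes, dtype=int))
        all_sizes.extend(sizes)
        spacing.extend(g for g, trans in gap_sizes(s, params) if trans)
    sizes_arr = np.asarray(all_sizes, dtype=int)
    return PelotonStats(
        sizes=sizes_arr,
        per_snapshot=per_snap,
        mean_size=float(sizes_arr.mean()) if sizes_arr.size else math.nan,
        spacing=np.asarray(spacing, dtype=int),
    )


# ---------------------------------------------------------------------------
# geometric (mixture) fits of the gap distribution


@dataclass
class GapDistribution:
    """Histogram of motor-motor gap sizes with geometric fits.

    A geometric law on {0, 1, 2, ...} with success parameter ``p`` has
    pmf ``p (1-p)^g``; the single-component fit corresponds to one
    underlying TASEP, the two-component mixture to the superposition of
    the intra-peloton and trans-peloton TASEPs.  Model preference is
    reported via BIC (and the likelihood-ratio statistic), not enforced.
    """

    values: np.ndarray
    counts: np.ndarray
    p_single: float
    loglik_single: float
    weight_intra: float
    p_intra: float
    p_trans: float
    loglik_mixture: float
    bic_single: float
    bic_mixture: float
    lrt: float
    preferred: str            # "single" | "mixture"
    degenerate: bool = False

    @property
    def n_gaps(self) -> int:
        return int(self.counts.sum())


def _geom_loglik(values: np.ndarray, counts: np.ndarray, p: float) -> float:
    if p <= 0 or p >= 1:
        # p == 1 is the degenerate all-zero-gap case
        if p == 1.0 and np.all(values[counts > 0] == 0):
            return 0.0
        return -math.inf
    return float(np.sum(counts * (math.log(p) + values * math.log1p(-p))))


def _mixture_em(
    values: np.ndarray,
    counts: np.ndarray,
    w0: float,
    p10: float,
    p20: float,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[float, float, float, float]:
    """Weighted EM for a two-component geometric mixture; returns
    ``(w, p1, p2, loglik)``."""
    w, p1, p2 = w0, p10, p20
    n = counts.sum()
    ll_old = -math.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            lf1 = math.log(p1) + values * math.log1p(-p1)
            lf2 = math.log(p2) + values * math.log1p(-p2)
        a = np.log(w) + lf1
        b = np.log1p(-w) + lf2
        m = np.maximum(a, b)
        lse = m + np.log(np.exp(a - m) + np.exp(b - m))
        r1 = np.exp(a - lse)
        ll = float(np.sum(counts * lse))
        n1 = float(np.sum(counts * r1))
        if n1 <= 0 or n1 >= n:
            break
        w = n1 / n
        mean1 = float(np.sum(counts * r1 * values)) / n1
        mean2 = float(np.sum(counts * (1 - r1) * values)) / (n - n1)
        p1 = 1.0 / (1.0 + mean1)
        p2 = 1.0 / (1.0 + mean2)
        p1 = min(max(p1, 1e-9), 1 - 1e-12)
        p2 = min(max(p2, 1e-9), 1 - 1e-12)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            ll_old = ll
            break
        ll_old = ll
    return w, p1, p2, ll_old


def fit_gap_distribution(
    gaps, n_restarts: int = 10, seed: int = 0
) -> GapDistribution:
    """Fit single-geometric and two-component geometric-mixture models to
    a sample of gap sizes by maximum likelihood (EM with random
    restarts for the mixture)."""
    gaps = np.asarray(list(gaps) if not isinstance(gaps, np.ndarray) else gaps,
                      dtype=int)
    if gaps.size == 0:
        raise ValueError("no gaps to fit")
    if np.any(gaps < 0):
        raise ValueError("gap sizes must be non-negative")
    values, counts = np.unique(gaps, return_counts=True)
    values = values.astype(float)
    counts = counts.astype(float)
    n = counts.sum()
    mean = float((values * counts).sum() / n)
    degenerate = bool(values.size == 1)

    p_single = 1.0 / (1.0 + mean)
    ll_single = _geom_loglik(values, counts, p_single)

    if degenerate:
        # all gaps identical: the mixture adds nothing
        bic_s = -2 * ll_single + 1 * math.log(n)
        return GapDistribution(
            values=values.astype(int), counts=counts.astype(int),
            p_single=p_single, loglik_single=ll_single,
            weight_intra=1.0, p_intra=p_single, p_trans=p_single,
            loglik_mixture=ll_single,
            bic_single=bic_s, bic_mixture=-2 * ll_single + 3 * math.log(n),
            lrt=0.0, preferred="single", degenerate=True,
        )

    rng = np.random.default_rng(seed)
    best = (-math.inf, 0.5, p_single, p_single)
    inits = [(0.5, min(0.9, 2 * p_single), max(1e-3, 0.5 * p_single))]
    for _ in range(n_restarts):
        inits.append((
            float(rng.uniform(0.2, 0.8)),
            float(rng.uniform(0.05, 0.95)),
            float(rng.uniform(0.05, 0.95)),
        ))
    for w0, p10, p20 in inits:
        w, p1, p2, ll = _mixture_em(values, counts, w0, p10, p20)
        if ll > best[0]:
            best = (ll, w, p1, p2)
    ll_mix, w, p1, p2 = best
    # orient: intra-peloton gaps are the smaller ones -> larger p
    if p1 < p2:
        p1, p2 = p2, p1
        w = 1.0 - w
    bic_s = -2 * ll_single + 1 * math.log(n)
    bic_m = -2 * ll_mix + 3 * math.log(n)
    return GapDistribution(
        values=values.astype(int), counts=counts.astype(int),
        p_single=p_single, loglik_single=ll_single,
        weight_intra=w, p_intra=p1, p_trans=p2, loglik_mixture=ll_mix,
        bic_single=bic_s, bic_mixture=bic_m,
        lrt=2.0 * max(0.0, ll_mix - ll_single),
        preferred="mixture" if bic_m < bic_s else "single",
    )


# ---------------------------------------------------------------------------
# density and velocity profiles


@dataclass
class ProfileEstimate:
    """Position-resolved steady-state profiles.

    ``rho_m``/``rho_rb`` are per-site occupation probabilities (a site is
    occupied when covered by a footprint); ``v_m(x)`` is the realized
    stepping velocity of motors whose front is at ``x`` (step events per
    second of front residence, a displacement velocity robust at low
    density).  ``x`` holds bin centres when ``bin_size > 1``.
    """

    x: np.ndarray
    rho_m: np.ndarray
    rho_rb: np.ndarray
    v_m: np.ndarray
    step_counts: np.ndarray
    front_time: np.ndarray
    n_snapshots: int
    bin_size: int


def _coverage(positions: np.ndarray, size: int, L: int, per: bool) -> np.ndarray:
    """Total number of footprints covering each site, summed over a batch
    of leftmost positions (diff-and-cumsum, O(n + L))."""
    diff = np.zeros(L + size + 1, dtype=np.int64)
    np.add.at(diff, positions, 1)
    np.add.at(diff, positions + size, -1)
    cov = np.cumsum(diff)
    out = cov[:L].astype(np.float64)
    if per:
        # footprints extending past site L-1 wrap onto the start of the ring
        tail = cov[L:L + size]
        out[: len(tail)] += tail
    return out


def estimate_profiles(
    trajectory: Trajectory,
    bin_size: int = 1,
    t0: float | None = None,
    t1: float | None = None,
    smooth: int | None = None,
) -> ProfileEstimate:
    """Time-averaged density and velocity profiles over ``[t0, t1)``.

    Densities come from the snapshot ensemble; velocities from replaying
    the event log (arrival/departure bookkeeping of every motor front).
    An optional moving-average ``smooth`` window (e.g. ``delta_rb``)
    mimics averaging over the size of a nucleosome.
    """
    params = trajectory.params
    L, dm, drb, per = params.L, params.delta_m, params.delta_rb, params.periodic
    t0 = trajectory.burn_in if t0 is None else t0
    t1 = trajectory.t_max if t1 is None else t1
    if not t0 < t1:
        raise ValueError("need t0 < t1")

    snaps = [s for s in trajectory.snapshots if t0 <= s.time < t1]
    n_snap = len(snaps)
    mpos = np.concatenate([np.asarray(s.motors, dtype=np.int64)
                           for s in snaps]) if n_snap else np.empty(0, int)
    rpos = np.concatenate([np.asarray(s.roadblocks, dtype=np.int64)
                           for s in snaps]) if n_snap else np.empty(0, int)
    rho_m = _coverage(mpos, dm, L, per) / max(n_snap, 1)
    rho_rb = _coverage(rpos, drb, L, per) / max(n_snap, 1)

    counts, ftime = _front_statistics(trajectory, t0, t1)

    if smooth:
        # edge-corrected moving average (positioned nucleosomes imprint
        # ~delta_rb-periodic oscillations that would dominate any fit)
        k = np.ones(smooth)
        norm = np.convolve(np.ones_like(rho_m), k, mode="same")
        rho_m = np.convolve(rho_m, k, mode="same") / norm
        rho_rb = np.convolve(rho_rb, k, mode="same") / norm

    if bin_size > 1:
        nb = L // bin_size
        sl = slice(0, nb * bin_size)
        x = (np.arange(nb) + 0.5) * bin_size
        rho_m = rho_m[sl].reshape(nb, bin_size).mean(axis=1)
        rho_rb = rho_rb[sl].reshape(nb, bin_size).mean(axis=1)
        cb = counts[sl].reshape(nb, bin_size).sum(axis=1)
        tb = ftime[sl].reshape(nb, bin_size).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(tb > 0, cb / tb, np.nan)
        counts_out, ftime_out = cb, tb
    else:
        x = np.arange(L, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(ftime > 0, counts / ftime, np.nan)
        counts_out, ftime_out = counts, ftime

    return ProfileEstimate(
        x=x, rho_m=rho_m, rho_rb=rho_rb, v_m=v,
        step_counts=counts_out, front_time=ftime_out,
        n_snapshots=n_snap, bin_size=bin_size,
    )


def _front_statistics(
    trajectory: Trajectory, t0: float, t1: float
) -> tuple[np.ndarray, np.ndarray]:
    """Replay the event log: per-site step counts and front residence
    time restricted to ``[t0, t1)``."""
    params = trajectory.params
    L, dm, per = params.L, params.delta_m, params.periodic
    counts = np.zeros(L, dtype=np.float64)
    ftime = np.zeros(L, dtype=np.float64)
    arrival: dict[int, float] = {}
    for p in trajectory.initial_state.motors:
        arrival[(p + dm - 1) % L if per else p + dm - 1] = 0.0

    def settle(front: int, a: float, d: float, stepped: bool) -> None:
        lo, hi = max(a, t0), min(d, t1)
        if hi > lo:
            ftime[front] += hi - lo
        if stepped and t0 <= d < t1:
            counts[front] += 1.0

    for t, kind, pos in zip(trajectory.times.tolist(),
                            trajectory.kinds.tolist(),
                            trajectory.positions.tolist()):
        if kind == STEP:
            new_front = (pos + dm - 1) % L if per else pos + dm - 1
            old_front = (new_front - 1) % L if per else new_front - 1
            settle(old_front, arrival.pop(old_front), t, True)
            arrival[new_front] = t
        elif kind == INITIATE:
            arrival[dm - 1] = t
        elif kind == TERMINATE:
            settle(L - 1, arrival.pop(L - 1), t, True)
    for front, a in arrival.items():
        settle(front, a, t1, False)
    return counts, ftime


@dataclass
class RelaxationFit:
    """Exponential-relaxation fit ``y(x) = A - B exp(-x / x_p)``."""

    x_p_hat: float
    amplitude: float
    offset: float

    @property
    def y0(self) -> float:
        return self.offset - self.amplitude


def fit_relaxation(
    x: np.ndarray, y: np.ndarray, x_p_guess: float
) -> RelaxationFit:
    """Least-squares fit of ``A - B exp(-x/x_p)`` over the peloton-forming
    region, estimated as the first ``4 * x_p_guess`` lattice points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (x <= 4.0 * x_p_guess) & np.isfinite(y)
    if mask.sum() < 4:
        raise ValueError("not enough points in the fitting region")
    xs, ys = x[mask], y[mask]

    def f(x, a, b, xp):
        return a - b * np.exp(-x / xp)

    a0 = float(ys[-max(1, len(ys) // 10):].mean())
    b0 = a0 - float(ys[: max(1, len(ys) // 20)].mean())
    popt, _ = optimize.curve_fit(
        f, xs, ys, p0=(a0, b0, x_p_guess),
        bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    return RelaxationFit(x_p_hat=float(popt[2]), amplitude=float(popt[1]),
                         offset=float(popt[0]))


# ---------------------------------------------------------------------------
# burst statistics


@dataclass
class BurstSeries:
    """Windowed counting statistics of a point process (event stream)."""

    window: float
    counts: np.ndarray
    fano: float
    mean_rate: float
    interarrivals: np.ndarray


def burst_statistics(
    event_times: np.ndarray,
    window: float = 60.0,
    t0: float | None = None,
    t1: float | None = None,
) -> BurstSeries:
    """Counts per time window, Fano factor (variance/mean of counts;
    > 1 signals bursting) and interarrival times for an event stream."""
    times = np.asarray(event_times, dtype=float)
    t0 = float(times.min()) if t0 is None and times.size else (t0 or 0.0)
    t1 = float(times.max()) if t1 is None and times.size else (t1 or window)
    if window <= 0:
        raise ValueError("window must be positive")
    n_win = max(1, int((t1 - t0) / window))
    sel = times[(times >= t0) & (times < t0 + n_win * window)]
    counts = np.histogram(sel, bins=n_win,
                          range=(t0, t0 + n_win * window))[0]
    mean = counts.mean() if counts.size else math.nan
    fano = float(counts.var(ddof=1) / mean) if counts.size > 1 and mean > 0 \
        else math.nan
    inter = np.diff(np.sort(sel)) if sel.size > 1 else np.empty(0)
    return BurstSeries(window=window, counts=counts, fano=fano,
                       mean_rate=mean / window if counts.size else math.nan,
                       interarrivals=inter)
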