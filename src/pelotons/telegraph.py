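"""Two-state (telegraph) promoter model and burst comparison.

The telegraph model is the standard phenomenological description of
bursty transcription: a promoter switches between an off-state (rate
``k_on`` to leave) and an on-state (rate ``k_off`` to leave) and produces
transcripts at rate ``k_tr`` while on.  The lattice model maps onto it
through :func:`pelotons.theory.burst_parameters`; this module provides an
exact simulator of the two-state process and distance measures between
its event stream and the lattice model's termination stream, so the
mapping can be checked without transcribing any external closed-form
noise formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .observables import burst_statistics
from .theory import BurstParams

__all__ = ["TelegraphParams", "simulate_telegraph", "BurstComparison",
           "compare_burstiness"]


@dataclass(frozen=True)
class TelegraphParams:
    """Switching and production rates of the two-state promoter (1/s)."""

    k_on: float
    k_off: float
    k_tr: float

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.k_tr) < 0:
            raise ValueError("telegraph rates must be >= 0")


def simulate_telegraph(
    params: TelegraphParams | BurstParams,
    t_max: float,
    seed: int | None = None,
    start_on: bool = False,
) -> np.ndarray:
    """Exact simulation of the telegraph process; returns production times.

    Production is Poisson at ``k_tr`` while the promoter is on.  The
    promoter starts in the off state by default (a fresh gene waiting for
    its first peloton, in the lattice-model analogy).
    """
    k_on, k_off, k_tr = params.k_on, params.k_off, params.k_tr
    rng = np.random.default_rng(seed)
    t = 0.0
    on = start_on
    out: list[float] = []
    while t < t_max:
        if on:
            total = k_off + k_tr
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= t_max:
                break
            if rng.random() * total < k_tr:
                out.append(t)
            else:
                on = False
        else:
            if k_on <= 0:
                break
            t += rng.exponential(1.0 / k_on)
            on = True
    return np.asarray(out)


@dataclass
class BurstComparison:
    """Distances between the lattice termination stream and the mapped
    telegraph stream; reported, not thresholded (the mapping is an
    approximation, not an identity)."""

    windows: np.ndarray
    fano_lattice: np.ndarray
    fano_telegraph: np.ndarray
    fano_distance: float       # mean |Fano_lattice - Fano_telegraph|
    ks_statistic: float        # Kolmogorov-Smirnov on interarrival times
    ks_pvalue: float
    rate_lattice: float        # events per second
    rate_telegraph: float

    def summary(self) -> str:
        lines = ["window_s\tfano_lattice\tfano_telegraph"]
        for w, fl, ft in zip(self.windows, self.fano_lattice,
                             self.fano_telegraph):
            lines.append(f"{w:g}\t{fl:.3f}\t{ft:.3f}")
        lines.append(f"# fano_distance={self.fano_distance:.3f} "
                     f"ks={self.ks_statistic:.3f} (p={self.ks_pvalue:.3g}) "
                     f"rates: lattice={self.rate_lattice:.4g}/s "
                     f"telegraph={self.rate_telegraph:.4g}/s")
        return "\n".join(lines)


def compare_burstiness(
    lattice_terminations: np.ndarray,
    mapped: BurstParams | TelegraphParams,
    t_max: float,
    seed: int | None = None,
    windows: tuple[float, ...] = (30.0, 60.0, 120.0, 300.0),
) -> BurstComparison:
    """Simulate the telegraph model at the mapped parameters and compare
    windowed Fano factors and interarrival distributions with the
    lattice model's termination stream."""
    term = np.asarray(lattice_terminations, dtype=float)
    tele = simulate_telegraph(mapped, t_max, seed=seed)
    f_lat, f_tel = [], []
    for w in windows:
        f_lat.append(burst_statistics(term, window=w).fano)
        f_tel.append(burst_statistics(tele, window=w).fano)
    f_lat = np.asarray(f_lat)
    f_tel = np.asarray(f_tel)
    ok = np.isfinite(f_lat) & np.isfinite(f_tel)
    dist = float(np.abs(f_lat[ok] - f_tel[ok]).mean()) if ok.any() else math.nan
    if term.size > 1 and tele.size > 1:
        ks = stats.ks_2samp(np.diff(np.sort(term)), np.diff(np.sort(tele)))
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = math.nan, math.nan
    span_t = term.max() - term.min() if term.size > 1 else math.nan
    span_g = tele.max() - tele.min() if tele.size > 1 else math.nan
    return BurstComparison(
        windows=np.asarray(windows),
        fano_lattice=f_lat,
        fano_telegraph=f_tel,
        fano_distance=dist,
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        rate_lattice=float(term.size / span_t) if span_t else math.nan,
        rate_telegraph=float(tele.size / span_g) if span_g else math.nan,
    )
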