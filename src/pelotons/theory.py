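"""Closed-form theory of peloton formation in the initiation-limited regime.

The heuristic theory rests on the roadblock shadow: a moving motor leaves
a region of size ``Delta = v_bulk * tau + delta_rb`` behind it that is
depleted of roadblocks, because the roadblock needs its full footprint
cleared plus its equilibration time ``tau`` to rebind.  The time for a
motor to open the shadow for rebinding is the effective rebinding time

    tau_Delta = Delta / k_tp = tau + delta_rb / k_tp ,

with ``v_bulk = k_tp`` once pelotons have formed.  From it follow the
average peloton size, the distance over which pelotons form, the relative
density and velocity profiles along the gene, and the mapping onto an
effective two-state (telegraph) promoter:

    n_p  = 1 + k_in * tau_Delta
    x_p  = (1/k_in) / (1/k_tp - 1/k_ip) / ln(1 + 1/(k_in * tau_Delta))
    k_tr = [k_in tau_Delta / (1 + k_in tau_Delta)] * k_tp / delta_m
    k_off = [1 / (1 + k_in tau_Delta)] * k_tp / delta_m
    k_on = 1 / tau_Delta

These are the printed initiation-limited limit forms; they assume motors
typically clear the initiation site between initiation attempts
(``k_in * delta_m / k_ip`` small).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ModelParams

__all__ = [
    "AnalyticPrediction",
    "BurstParams",
    "effective_rebinding_time",
    "roadblock_shadow",
    "peloton_size",
    "peloton_formation_distance",
    "relative_profiles",
    "burst_parameters",
    "bulk_peloton_scale",
    "predict",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (printing convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def effective_rebinding_time(tau: float, delta_rb: int, k_tp: float) -> float:
    """Time ``tau_Delta = tau + delta_rb / k_tp`` for a motor to clear the
    roadblock shadow and let a roadblock rebind behind it (s)."""
    if k_tp <= 0:
        raise ValueError("k_tp must be positive")
    if tau < 0 or delta_rb < 0:
        raise ValueError("tau and delta_rb must be non-negative")
    return tau + delta_rb / k_tp


def roadblock_shadow(v_bulk: float, tau: float, delta_rb: int) -> float:
    """Size of the roadblock-depleted region trailing a motor,
    ``Delta = v_bulk * tau + delta_rb`` (sites)."""
    return v_bulk * tau + delta_rb


def peloton_size(k_in: float, tau_delta: float) -> float:
    """Average number of motors per peloton, ``n_p = 1 + k_in * tau_Delta``.

    ``n_p - 1`` counts the motors initiated during one effective
    roadblock-rebinding time, i.e. before a roadblock reappears at the
    start of the track and starts a new peloton.
    """
    if k_in < 0:
        raise ValueError("k_in must be >= 0")
    return 1.0 + k_in * tau_delta


def peloton_formation_distance(
    k_in: float, k_tp: float, k_ip: float, tau_delta: float
) -> float:
    """Distance ``x_p`` (sites) over which the initial pelotons form.

    The last motor of a nascent peloton gains ``1/k_tp - 1/k_ip`` seconds
    per step on the slowed motors ahead; ``x_p`` is the number of steps
    needed to close the typical initiation headway.
    """
    if k_in <= 0:
        raise ValueError("k_in must be positive for peloton formation")
    if not k_ip > k_tp:
        raise ValueError("need k_ip > k_tp (no catching up otherwise)")
    return (1.0 / k_in) / (1.0 / k_tp - 1.0 / k_ip) \
        / math.log(1.0 + 1.0 / (k_in * tau_delta))


def relative_profiles(
    x: np.ndarray | float, params: ModelParams, v_bulk: float | None = None
):
    """Relative motor-density, motor-velocity, and roadblock-density
    profiles along the track (Eq.-2-type exponential relaxation).

    Returns ``(rho_m(x)/rho_m, v_m(x)/v_m, rho_rb(x)/rho_rb)``; each
    ratio approaches 1 over the peloton-formation length ``x_p``.  The
    absolute final velocity is ``v_bulk`` (default ``k_tp``).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    p = _prediction_inputs(params, v_bulk)
    f = p.k_in_tau / (1.0 + p.k_in_tau)
    decay = np.exp(-x / p.x_p)
    rho_m = 1.0 - f * (1.0 - params.k_tp / params.k_ip) * decay
    v_m = 1.0 + f * (params.k_ip / params.k_tp - 1.0) * decay
    rho_rb = 1.0 - p.k_in_tau / (
        math.exp(params.delta_rb / p.x_p) + p.k_in_tau) * decay
    return rho_m, v_m, rho_rb


@dataclass(frozen=True)
class BurstParams:
    """Effective two-state promoter parameters (all 1/s).

    ``k_tr`` is the production rate while "on", ``k_on``/``k_off`` the
    switching rates.  The identity ``k_tr + k_off = k_tp / delta_m``
    holds exactly: the on-state production and the off-switch compete for
    the same peloton-passage events at the terminator.
    """

    k_tr: float
    k_on: float
    k_off: float


def burst_parameters(
    k_in: float, tau_delta: float, k_tp: float, delta_m: int
) -> BurstParams:
    """Map the lattice model onto the telegraph model (Eq.-3-type limit).

    A peloton passing termination produces motors at rate
    ``k_tp / delta_m`` (the on-state rate is shared between production,
    weight ``k_in tau_Delta / (1 + k_in tau_Delta)``, and switching off);
    the off-state ends when the next peloton arrives, at the inverse
    effective rebinding time.
    """
    if tau_delta <= 0 or k_tp <= 0 or delta_m < 1:
        raise ValueError("tau_delta, k_tp must be positive, delta_m >= 1")
    kt = k_in * tau_delta
    base = k_tp / delta_m
    return BurstParams(
        k_tr=kt / (1.0 + kt) * base,
        k_off=1.0 / (1.0 + kt) * base,
        k_on=1.0 / tau_delta,
    )


def bulk_peloton_scale(k_ip: float, k_tp: float, shadow: float) -> float:
    """Scale ``(k_ip/k_tp)**(Delta/2)`` of the steady-state bulk peloton.

    A proportionality only (the prefactor is not fixed by the heuristic
    argument); at physiological parameters it is astronomically large,
    which is why pelotons formed near initiation never re-equilibrate
    over a finite gene.
    """
    if not 0 < k_tp <= k_ip:
        raise ValueError("need 0 < k_tp <= k_ip")
    return (k_ip / k_tp) ** (shadow / 2.0)


@dataclass(frozen=True)
class AnalyticPrediction:
    """All closed-form observables for one parameter set.

    Rates are 1/s, lengths in sites; ``v_m_final`` is the bulk velocity
    in sites/s.  ``k_in_tau`` is the dimensionless burst-significance
    parameter ``k_in * tau_Delta`` (pelotons require it > 1).
    """

    tau: float
    tau_delta: float
    shadow: float
    n_p: float
    x_p: float
    v_m_final: float
    v_m_initial: float
    k_tr: float
    k_on: float
    k_off: float
    k_in_tau: float
    bulk_scale: float

    def to_dict(self) -> dict[str, float]:
        return {
            "tau_s": self.tau,
            "tau_delta_s": self.tau_delta,
            "shadow_sites": self.shadow,
            "n_p": self.n_p,
            "x_p_sites": self.x_p,
            "v_m_final": self.v_m_final,
            "v_m_initial": self.v_m_initial,
            "k_tr_per_s": self.k_tr,
            "k_on_per_s": self.k_on,
            "k_off_per_s": self.k_off,
            "k_in_tau_delta": self.k_in_tau,
            "bulk_peloton_scale": self.bulk_scale,
        }


def _prediction_inputs(params: ModelParams, v_bulk: float | None) -> AnalyticPrediction:
    return predict(params, v_bulk=v_bulk)


def predict(params: ModelParams, v_bulk: float | None = None) -> AnalyticPrediction:
    """Evaluate the full analytic prediction for ``params``.

    ``tau`` is taken from ``params.tau`` when set, else from the binding
    process as ``1/k_b``.  ``v_bulk`` defaults to ``k_tp`` (the average
    velocity once pelotons have formed); an explicit value can be passed
    for exploratory use outside the peloton-forming regime.
    """
    if v_bulk is None:
        v_bulk = params.k_tp
    tau = params.tau_eff
    if not math.isfinite(tau):
        raise ValueError(
            "no finite equilibration time: set params.tau or a positive k_b")
    shadow = roadblock_shadow(v_bulk, tau, params.delta_rb)
    tau_delta = shadow / params.k_tp
    n_p = peloton_size(params.k_in, tau_delta)
    if params.k_in > 0 and params.k_ip > params.k_tp:
        x_p = peloton_formation_distance(
            params.k_in, params.k_tp, params.k_ip, tau_delta)
    else:
        x_p = math.inf
    bp = burst_parameters(params.k_in, tau_delta, params.k_tp, params.delta_m)
    kt = params.k_in * tau_delta
    f = kt / (1.0 + kt)
    v0 = params.k_tp * (1.0 + f * (params.k_ip / params.k_tp - 1.0))
    return AnalyticPrediction(
        tau=tau,
        tau_delta=tau_delta,
        shadow=shadow,
        n_p=n_p,
        x_p=x_p,
        v_m_final=params.k_tp,
        v_m_initial=v0,
        k_tr=bp.k_tr,
        k_on=bp.k_on,
        k_off=bp.k_off,
        k_in_tau=kt,
        bulk_scale=bulk_peloton_scale(params.k_ip, params.k_tp, shadow),
    )
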