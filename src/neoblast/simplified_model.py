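"""Single-differentiated-class model and its closed-form steady state.

With one class of differentiated cells and an instantaneous
progenitor-to-differentiated transition the dynamics reduce to

    N(t+1) = N [1 + p1 a1 - p3 fD fN a3]
    D(t+1) = D exp(-mu - mu_Q) + N fD [p2 a2 + 2 p3 fN a3]
    Q(t+1) = Q + Y_e D^delta + gamma D (1 - exp(-mu - mu_Q))
               - m_r (N + D) - m_d N [p1 a1 + fD (p2 a2 + fN p3 a3)]

Mortality is a constant baseline mu (plus the resource-dependent term
mu_Q), not the level/proportion logistics of the full model: with a
single class the proportion is identically 1, so that machinery is
degenerate here.

Under sufficient resources the steady state has f_D(D_bar) = p1/p3,
giving alpha = (p3/p1 - 1)/D_bar, a neoblast/differentiated ratio

    eta = N_bar/D_bar = (1 - exp(-mu)) p3 / (p1 (p2 + 2 p3))

(a food-independent neoblast fraction eta/(eta+1)), and a resource
balance fixing D_bar:

    D_bar^(1-delta) = Y_e / [ m_r (eta + 1)
                        + m_d eta (p1 + (p1/p3)(p2 + p3))
                        - gamma (1 - exp(-mu)) ]
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleParametersError
from .feedback import FeedbackValues, a_gate, compute_thresholds, f_N, f_Q, mu_Q
from .full_model import StepDiagnostics, _gate, _partition
from .params import Parameters, validate
from .steady_state import Calibration, size_from_cells
from .trajectory import Trajectory

__all__ = [
    "SimpleState",
    "SimpleSteadyState",
    "simple_steady_state",
    "simple_calibration",
    "simple_step",
    "simulate_simple",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimpleState:
    """Simplified-model state at one time step."""

    t: int
    N: float
    D: float
    Q: float = 0.0

    def __post_init__(self):
        if self.N < 0.0 or self.D < 0.0 or self.Q < 0.0:
            raise ValueError("all state components must be non-negative")


@dataclass(frozen=True)
class SimpleSteadyState:
    """Closed-form sufficient-resources steady state, one class."""

    eta: float
    D_bar: float
    N_bar: float
    alpha: float
    neoblast_fraction: float
    size_mm: float
    Y_e: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def simple_steady_state(Y_e: float, params: Parameters) -> SimpleSteadyState:
    """Solve the simplified model's closed-form steady state.

    Raises InfeasibleParametersError if the resource-balance denominator
    is non-positive.
    """
    validate(params.replace(I=1, s=(1.0,)))
    if Y_e <= 0.0:
        raise InfeasibleParametersError(f"Y_e must be positive; got {Y_e}")
    p = params
    turnover = -math.expm1(-p.mu)  # 1 - e^{-mu}
    eta = turnover * p.p3 / (p.p1 * (p.p2 + 2.0 * p.p3))
    phi_bar = p.p1 / p.p3
    denom = (
        p.m_r * (eta + 1.0)
        + p.m_d * eta * (p.p1 + phi_bar * (p.p2 + p.p3))
        - p.gamma * turnover
    )
    if denom <= 0.0:
        raise InfeasibleParametersError(
            "resource balance has non-positive denominator "
            f"({denom}); recycling exceeds costs, no steady state"
        )
    D_bar = (Y_e / denom) ** (1.0 / (1.0 - p.delta))
    N_bar = eta * D_bar
    alpha = (p.p3 / p.p1 - 1.0) / D_bar
    return SimpleSteadyState(
        eta=eta,
        D_bar=D_bar,
        N_bar=N_bar,
        alpha=alpha,
        neoblast_fraction=eta / (eta + 1.0),
        size_mm=size_from_cells(D_bar),
        Y_e=Y_e,
    )


def simple_calibration(Y_e: float, params: Parameters) -> Calibration:
    """Feedback calibration of the simplified model for one food level.

    Single-class analogue of the full model's calibration; sigma_D and
    sigma_rho are carried for schema compatibility but unused by the
    constant-mortality simplified dynamics.
    """
    ss = simple_steady_state(Y_e, params)
    return Calibration(
        D_bar=np.array([ss.D_bar]),
        rho_bar=np.array([1.0]),
        alpha=np.array([ss.alpha]),
        N_c=params.c_N * ss.N_bar,
        sigma_N=params.c_N * ss.N_bar,
        sigma_D=np.array([params.c_D * ss.D_bar]),
        sigma_rho=np.array([params.c_D]),
        Y_e=Y_e,
    )


def _evaluate_simple(state: SimpleState, calib: Calibration, params: Parameters) -> dict:
    p = params
    n, d, q = state.N, state.D, state.Q
    fD = 1.0 / (1.0 + float(calib.alpha[0]) * d)
    fN = f_N(n, calib.N_c, calib.sigma_N)
    if p.sufficient_resources:
        thr = None
        a1 = a2 = a3 = 1.0
        fQ = 1.0
        muQ = 0.0
    else:
        thr = compute_thresholds(n, [d], fD, fN, p)
        a1 = _gate(q, thr.q1, thr.q12, p.hill_exponent)
        a2 = _gate(q, thr.q2, thr.q23, p.hill_exponent)
        a3 = _gate(q, thr.q3, thr.q34, p.hill_exponent)
        fQ = f_Q(q, p.beta_Q)
        muQ = mu_Q(q, thr, p.mu_Q_max)
    fb = FeedbackValues(fD=fD, fN=fN, fQ=fQ, a1=a1, a2=a2, a3=a3, muQ=muQ)
    M = p.mu + muQ
    deaths = d * -math.expm1(-M)
    influx = n * fD * (p.p2 * a2 + 2.0 * p.p3 * fN * a3)
    if p.sufficient_resources:
        fluxes = (0.0, 0.0, 0.0, 0.0)
    else:
        fluxes = (
            p.Y_e * d ** p.delta,
            p.gamma * deaths,
            -p.m_r * (n + d),
            -p.m_d * n * (p.p1 * a1 + fD * (p.p2 * a2 + fN * p.p3 * a3)),
        )
    return {
        "fb": fb,
        "thr": thr,
        "M": M,
        "deaths": deaths,
        "influx": influx,
        "fluxes": fluxes,
        "size_mm": size_from_cells(d) if d > 0.0 else float("nan"),
        "neoblast_fraction": n / (n + d) if n + d > 0.0 else float("nan"),
    }


def _diag_simple(ev: dict, q_clamp: float = 0.0) -> StepDiagnostics:
    nan = np.array([float("nan")])
    return StepDiagnostics(
        feedback=ev["fb"],
        thresholds=ev["thr"],
        P_total=ev["influx"],
        M=np.array([ev["M"]]),
        deaths=np.array([ev["deaths"]]),
        level_share=nan.copy(),
        proportion_share=nan.copy(),
        flux_food=ev["fluxes"][0],
        flux_recycle=ev["fluxes"][1],
        flux_maintenance=ev["fluxes"][2],
        flux_division=ev["fluxes"][3],
        q_clamp=q_clamp,
        size_mm=ev["size_mm"],
        neoblast_fraction=ev["neoblast_fraction"],
    )


def simple_step(
    state: SimpleState, calib: Calibration, params: Parameters
) -> tuple[SimpleState, StepDiagnostics]:
    """Advance the simplified model by one step.

    Mortality shares (level/proportion) are reported as NaN: constant
    baseline mortality has no deviation partition.
    """
    p = params
    ev = _evaluate_simple(state, calib, p)
    fb = ev["fb"]
    N_next = state.N * (1.0 + p.p1 * fb.a1 - p.p3 * fb.fD * fb.fN * fb.a3)
    D_next = state.D * math.exp(-ev["M"]) + ev["influx"]
    q_clamp = 0.0
    if p.sufficient_resources:
        Q_next = state.Q
    else:
        Q_next = state.Q + sum(ev["fluxes"])
        if Q_next < 0.0:
            q_clamp = -Q_next
            Q_next = 0.0
            logger.warning(
                "resource pool clamped at 0 at step %d (deficit %.6g)",
                state.t, q_clamp,
            )
    return SimpleState(t=state.t + 1, N=N_next, D=D_next, Q=Q_next), _diag_simple(ev, q_clamp)


def _record(traj: Trajectory, state: SimpleState, diag: StepDiagnostics, Y_e: float) -> None:
    fb = diag.feedback
    traj.append({
        "t": state.t, "scaled_t": state.t / 10000.0,
        "N": state.N, "D_1": state.D, "Q": state.Q,
        "size_mm": diag.size_mm, "neoblast_fraction": diag.neoblast_fraction,
        "fD": fb.fD, "fN": fb.fN, "fQ": fb.fQ,
        "a1": fb.a1, "a2": fb.a2, "a3": fb.a3,
        "P_total": diag.P_total, "M_1": float(diag.M[0]),
        "deaths_total": float(diag.deaths[0]),
        "level_share_1": float("nan"), "proportion_share_1": float("nan"),
        "Y_e": Y_e,
    })


def simulate_simple(
    state0: SimpleState,
    calib: Calibration,
    params: Parameters,
    n_steps: int,
    *,
    food_changes: dict[int, float] | None = None,
    recalibrate: bool = True,
    record_stride: int = 100,
) -> Trajectory:
    """Iterate :func:`simple_step`; same recording and food-schedule
    semantics as :func:`neoblast.full_model.simulate`."""
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1; got {n_steps}")
    traj = Trajectory(1)
    state = state0
    food_changes = food_changes or {}
    for _ in range(n_steps):
        if state.t in food_changes:
            new_Y = food_changes[state.t]
            params = params.replace(Y_e=new_Y)
            if recalibrate:
                calib = simple_calibration(new_Y, params)
            logger.info(
                "step %d: food changed to Y_e=%g%s",
                state.t, new_Y, "" if not recalibrate else " (recalibrated)",
            )
        next_state, diag = simple_step(state, calib, params)
        if state.t % record_stride == 0:
            _record(traj, state, diag, params.Y_e)
        state = next_state
    _record(traj, state, _diag_simple(_evaluate_simple(state, calib, params)), params.Y_e)
    traj.final_state = state
    traj.final_calib = calib
    traj.final_params = params
    return traj
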