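"""One-step update and trajectory simulation of the full model.

State is (N, D_1..D_I, Q): neoblasts, I classes of differentiated
cells, and the internal resource pool. Each step applies

    N(t+1)   = N [1 + p1 a1 - p3 fD fN a3]
    D_i(t+1) = D_i exp(-M_i) + fQ * P * weight_i
    Q(t+1)   = Q + food gain + recycling - maintenance - division cost

where P = N fD [p2 a2 + 2 p3 fN a3] is progeny production, the
allocation weights follow the relative-need rule (progeny go to the
classes furthest below their homeostatic targets), and the mortality
rate M_i combines a resource-dependent term with two logistic terms
penalizing deviation of the class count from its target level and of
the class proportion from its target mix.

In sufficient-resources mode (the default) all resource gates are 1,
every progeny completes differentiation, resource-dependent death is
off, and Q is not updated — the dynamics depend on cell numbers only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateStateError
from .feedback import (
    FeedbackValues,
    ResourceThresholds,
    a_gate,
    compute_thresholds,
    f_D,
    f_N,
    f_Q,
    logistic,
    mu_Q,
)
from .params import Parameters
from .steady_state import Calibration, make_calibration, size_from_cells, solve_full_steady_state
from .trajectory import Trajectory

__all__ = [
    "FullState",
    "StepDiagnostics",
    "mortality_rates",
    "mortality_partition",
    "progeny_production",
    "relative_need_allocation",
    "step",
    "diagnose",
    "simulate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FullState:
    """Full-model state at one time step."""

    t: int
    N: float
    D: np.ndarray
    Q: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))
        if self.N < 0.0 or self.Q < 0.0 or np.any(self.D < 0.0):
            raise ValueError("all state components must be non-negative")


@dataclass(frozen=True)
class StepDiagnostics:
    """Per-step diagnostics of the transition leaving one state."""

    feedback: FeedbackValues
    thresholds: ResourceThresholds | None
    P_total: float
    M: np.ndarray
    deaths: np.ndarray
    level_share: np.ndarray
    proportion_share: np.ndarray
    flux_food: float
    flux_recycle: float
    flux_maintenance: float
    flux_division: float
    q_clamp: float
    size_mm: float
    neoblast_fraction: float


def relative_need_allocation(d, D_bar, *, floor: float | None = None) -> np.ndarray:
    """Progeny allocation weights by relative need.

    weight_i = (D_bar_i / d_i) / sum_k (D_bar_k / d_k); classes furthest
    below their homeostatic target receive the largest share. With
    ``floor`` set, counts are floored at that value inside the ratio
    only (perturbation protocols can drive classes arbitrarily close to
    zero); without it, any d_i <= 0 raises DegenerateStateError.
    """
    d = np.asarray(d, dtype=float)
    D_bar = np.asarray(D_bar, dtype=float)
    if floor is not None:
        d = np.maximum(d, floor)
    if np.any(d <= 0.0):
        raise DegenerateStateError(
            "relative need is undefined for an empty differentiated class"
        )
    needs = D_bar / d
    return needs / needs.sum()


def _mortality_terms(
    d: np.ndarray, calib: Calibration, params: Parameters, mortality_terms: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (M_without_muQ, level_logistic, proportion_logistic).

    ``mortality_terms``: "both" (level + proportion logistics, the full
    model), "level_only", or "constant" (M_i = mu_i, the simplified
    model's baseline; used for cross-model equivalence runs).
    """
    mu_i = np.array(params.mu_i, dtype=float)
    if mortality_terms == "constant":
        z = np.zeros_like(mu_i)
        return mu_i, z, z
    total = d.sum()
    if total <= 0.0:
        raise DegenerateStateError(
            "mortality rates are undefined with zero differentiated cells "
            "(class proportions do not exist)"
        )
    level = np.array(
        [logistic(x) for x in (d - calib.D_bar) / calib.sigma_D], dtype=float
    )
    if mortality_terms == "level_only":
        return mu_i * level, level, np.zeros_like(level)
    rho = d / total
    prop = np.array(
        [logistic(x) for x in (rho - calib.rho_bar) / calib.sigma_rho], dtype=float
    )
    return mu_i * (level + prop), level, prop


def mortality_rates(
    state: FullState,
    calib: Calibration,
    params: Parameters,
    *,
    mortality_terms: str = "both",
) -> np.ndarray:
    """Per-class per-step mortality rates M_i at the current state.

    M_i = mu_Q + mu_i [logistic((d_i - D_bar_i)/sigma_D_i)
                       + logistic((rho_i - rho_bar_i)/sigma_rho_i)].
    At homeostasis (d = D_bar, rho = rho_bar, ample resources) the two
    logistics are each 0.5, so M_i = mu_i.
    """
    base, _, _ = _mortality_terms(state.D, calib, params, mortality_terms)
    muQ = 0.0
    if not params.sufficient_resources and params.mu_Q_max > 0.0:
        fD = f_D(state.D, calib.alpha)
        fN = f_N(state.N, calib.N_c, calib.sigma_N)
        thr = compute_thresholds(state.N, state.D, fD, fN, params)
        muQ = mu_Q(state.Q, thr, params.mu_Q_max)
    return muQ + base


def mortality_partition(
    state: FullState, calib: Calibration, params: Parameters
) -> np.ndarray:
    """Per-class (level_share, proportion_share) of non-resource mortality.

    The two logistic terms of the mortality rate are normalized to sum
    to one, attributing deaths to cell-number imbalance vs mix
    imbalance. At homeostasis both terms equal 0.5 so the shares are
    (0.5, 0.5); if both terms vanish the shares are defined as
    (0.5, 0.5).
    """
    _, level, prop = _mortality_terms(state.D, calib, params, "both")
    return _partition(level, prop)


def _partition(level: np.ndarray, prop: np.ndarray) -> np.ndarray:
    tot = level + prop
    shares = np.empty((len(level), 2))
    for i, t in enumerate(tot):
        if t == 0.0:
            shares[i] = (0.5, 0.5)
        else:
            shares[i] = (level[i] / t, prop[i] / t)
    return shares


def progeny_production(
    state: FullState, calib: Calibration, params: Parameters, fb: FeedbackValues
) -> float:
    """Total progeny produced this step: N fD [p2 a2 + 2 p3 fN a3]."""
    return state.N * fb.fD * (
        params.p2 * fb.a2 + 2.0 * params.p3 * fb.fN * fb.a3
    )


def _gate(q: float, lower: float, mid: float, exponent: float) -> float:
    # a degenerate gate (mid == lower) means the division class is fully
    # suppressed by upstream factors (n = 0 or fD = 0); its value is moot
    if mid <= lower:
        return 0.0
    return a_gate(q, lower, mid, exponent)


def _evaluate(
    state: FullState,
    calib: Calibration,
    params: Parameters,
    mortality_terms: str,
) -> dict:
    """All per-step quantities at ``state`` without advancing it."""
    p = params
    n, d, q = state.N, state.D, state.Q
    fD = f_D(d, calib.alpha)
    fN = f_N(n, calib.N_c, calib.sigma_N)
    if p.sufficient_resources:
        thr = None
        a1 = a2 = a3 = 1.0
        fQ = 1.0
        muQ = 0.0
    else:
        thr = compute_thresholds(n, d, fD, fN, p)
        a1 = _gate(q, thr.q1, thr.q12, p.hill_exponent)
        a2 = _gate(q, thr.q2, thr.q23, p.hill_exponent)
        a3 = _gate(q, thr.q3, thr.q34, p.hill_exponent)
        fQ = f_Q(q, p.beta_Q)
        muQ = mu_Q(q, thr, p.mu_Q_max)
    fb = FeedbackValues(fD=fD, fN=fN, fQ=fQ, a1=a1, a2=a2, a3=a3, muQ=muQ)

    base, level, prop = _mortality_terms(d, calib, p, mortality_terms)
    M = muQ + base
    deaths = d * -np.expm1(-M)
    P = n * fD * (p.p2 * a2 + 2.0 * p.p3 * fN * a3)
    weights = relative_need_allocation(d, calib.D_bar, floor=p.allocation_floor)

    if p.sufficient_resources:
        flux_food = flux_recycle = flux_maint = flux_div = 0.0
    else:
        flux_food = p.Y_e * d[0] ** p.delta
        flux_recycle = p.gamma_p * (1.0 - fQ) * P + p.gamma * float(deaths.sum())
        flux_maint = -p.m_r * (n + float(d.sum()))
        flux_div = -p.m_d * n * (p.p1 * a1 + fD * (p.p2 * a2 + fN * p.p3 * a3))

    d_total = float(d.sum())
    return {
        "fb": fb,
        "thr": thr,
        "M": M,
        "deaths": deaths,
        "level": level,
        "prop": prop,
        "P": P,
        "weights": weights,
        "fluxes": (flux_food, flux_recycle, flux_maint, flux_div),
        "size_mm": size_from_cells(d_total) if d_total > 0.0 else float("nan"),
        "neoblast_fraction": n / (n + d_total) if n + d_total > 0.0 else float("nan"),
    }


def _diag_from_eval(ev: dict, q_clamp: float = 0.0) -> StepDiagnostics:
    shares = _partition(ev["level"], ev["prop"])
    return StepDiagnostics(
        feedback=ev["fb"],
        thresholds=ev["thr"],
        P_total=ev["P"],
        M=ev["M"],
        deaths=ev["deaths"],
        level_share=shares[:, 0],
        proportion_share=shares[:, 1],
        flux_food=ev["fluxes"][0],
        flux_recycle=ev["fluxes"][1],
        flux_maintenance=ev["fluxes"][2],
        flux_division=ev["fluxes"][3],
        q_clamp=q_clamp,
        size_mm=ev["size_mm"],
        neoblast_fraction=ev["neoblast_fraction"],
    )


def step(
    state: FullState,
    calib: Calibration,
    params: Parameters,
    *,
    mortality_terms: str = "both",
) -> tuple[FullState, StepDiagnostics]:
    """Advance the full model by one step.

    Returns the next state and the diagnostics of the transition. In
    sufficient-resources mode Q is carried through unchanged and all
    resource fluxes are reported as zero. In resource-tracking mode a
    transiently negative pool is clamped at zero (logged, and reported
    in ``StepDiagnostics.q_clamp``); the resource gates already
    suppress divisions before this point.
    """
    p = params
    ev = _evaluate(state, calib, p, mortality_terms)
    fb = ev["fb"]
    N_next = state.N * (1.0 + p.p1 * fb.a1 - p.p3 * fb.fD * fb.fN * fb.a3)
    D_next = state.D * np.exp(-ev["M"]) + fb.fQ * ev["P"] * ev["weights"]
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
    next_state = FullState(t=state.t + 1, N=N_next, D=D_next, Q=Q_next)
    return next_state, _diag_from_eval(ev, q_clamp)


def diagnose(
    state: FullState,
    calib: Calibration,
    params: Parameters,
    *,
    mortality_terms: str = "both",
) -> StepDiagnostics:
    """Diagnostics at ``state`` without advancing the model."""
    return _diag_from_eval(_evaluate(state, calib, params, mortality_terms))


def _record(traj: Trajectory, state: FullState, diag: StepDiagnostics, Y_e: float) -> None:
    fb = diag.feedback
    row = {"t": state.t, "scaled_t": state.t / 10000.0, "N": state.N}
    for i, di in enumerate(state.D, start=1):
        row[f"D_{i}"] = float(di)
    row.update(
        Q=state.Q,
        size_mm=diag.size_mm,
        neoblast_fraction=diag.neoblast_fraction,
        fD=fb.fD, fN=fb.fN, fQ=fb.fQ, a1=fb.a1, a2=fb.a2, a3=fb.a3,
        P_total=diag.P_total,
        deaths_total=float(diag.deaths.sum()),
        Y_e=Y_e,
    )
    for i in range(len(state.D)):
        row[f"M_{i + 1}"] = float(diag.M[i])
        row[f"level_share_{i + 1}"] = float(diag.level_share[i])
        row[f"proportion_share_{i + 1}"] = float(diag.proportion_share[i])
    traj.append(row)


def simulate(
    state0: FullState,
    calib: Calibration,
    params: Parameters,
    n_steps: int,
    *,
    food_changes: dict[int, float] | None = None,
    recalibrate: bool = True,
    record_stride: int = 100,
    mortality_terms: str = "both",
) -> Trajectory:
    """Iterate :func:`step` for ``n_steps``, recording every
    ``record_stride`` steps plus the final state.

    ``food_changes`` maps absolute step indices to new Y_e values; at
    each change Y_e is updated and (unless ``recalibrate=False``) the
    homeostatic targets, feedback strengths, and widths are recomputed
    from the steady state of the new food level.

    The returned :class:`~neoblast.trajectory.Trajectory` additionally
    carries ``final_state``, ``final_calib``, and ``final_params``
    attributes so runs can be chained (e.g. around a perturbation).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1; got {n_steps}")
    if len(state0.D) != params.I:
        raise ValueError(f"state has {len(state0.D)} classes; params.I={params.I}")
    traj = Trajectory(params.I)
    state = state0
    food_changes = food_changes or {}
    try:
        for _ in range(n_steps):
            if state.t in food_changes:
                new_Y = food_changes[state.t]
                params = params.replace(Y_e=new_Y)
                if recalibrate:
                    calib = make_calibration(
                        solve_full_steady_state(new_Y, params), params
                    )
                logger.info(
                    "step %d: food changed to Y_e=%g%s",
                    state.t, new_Y, "" if not recalibrate else " (recalibrated)",
                )
            next_state, diag = step(
                state, calib, params, mortality_terms=mortality_terms
            )
            if state.t % record_stride == 0:
                _record(traj, state, diag, params.Y_e)
            state = next_state
        _record(traj, state, diagnose(state, calib, params,
                                      mortality_terms=mortality_terms), params.Y_e)
    except DegenerateStateError as e:
        raise DegenerateStateError(f"at step {state.t}: {e}") from e
    traj.final_state = state
    traj.final_calib = calib
    traj.final_params = params
    return traj
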