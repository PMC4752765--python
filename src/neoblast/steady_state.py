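"""Closed-form steady state of the full model under sufficient resources,
food-dependent calibration of the feedback constants, and the
size/cell-number allometry.

At the steady state all the feedback values 1/(1+alpha_i D_bar_i) share
the common value phi_bar = p1/p3, which balances the neoblast update.
Each differentiated class then satisfies a production/mortality balance
that fixes the ratio w_i = D_bar_i / N_bar:

    w_i = phi_bar (p2 + 2 p3) / (I (1 - exp(-mu_i)))

so the steady-state neoblast fraction 1/(1 + sum w_i) depends only on
the transition rates and mortality rates — not on food. Food enters
through the resource balance, which yields

    N_bar^(1-delta) = Y_e w_1^delta / [ m_r (1 + sum w_i)
                        + m_d (p1 + phi_bar (p2 + p3))
                        - gamma sum w_i (1 - exp(-mu_i)) ]

The feedback strengths alpha_i = (1/phi_bar - 1)/D_bar_i therefore
emerge as food-dependent: richer environments support more cells and
need weaker per-cell inhibition.

Body size follows an allometric regression of planarian length on
differentiated-cell number:

    ln S(mm) = -3.8373 + 0.46582 ln(sum_i D_i)

Neoblasts do not contribute to size.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleParametersError
from .feedback import f_D
from .params import Parameters, validate

__all__ = [
    "ALLOMETRY_INTERCEPT",
    "ALLOMETRY_SLOPE",
    "SteadyStateSolution",
    "Calibration",
    "solve_full_steady_state",
    "make_calibration",
    "size_from_cells",
    "size_food_curve",
    "alpha_vs_food",
]

# ln(size in mm) regressed on ln(total differentiated cells); fitted to
# published counts for 4-16 mm animals and taken here as fixed constants.
ALLOMETRY_INTERCEPT = -3.8373
ALLOMETRY_SLOPE = 0.46582


@dataclass(frozen=True)
class SteadyStateSolution:
    """Full-model steady state for one food level."""

    phi_bar: float
    w: np.ndarray
    N_bar: float
    D_bar: np.ndarray
    rho_bar: np.ndarray
    neoblast_fraction: float
    alpha: np.ndarray
    P_bar: float
    size_mm: float
    Y_e: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class Calibration:
    """Homeostatic targets and feedback-shape constants for one food level.

    Produced by :func:`make_calibration`; consumed by the step functions.
    All widths are fractions (c_N, c_D) of the corresponding steady
    values, so the calibration — like the feedback strengths alpha —
    is food-dependent and is recomputed whenever Y_e changes.
    """

    D_bar: np.ndarray
    rho_bar: np.ndarray
    alpha: np.ndarray
    N_c: float
    sigma_N: float
    sigma_D: np.ndarray
    sigma_rho: np.ndarray
    Y_e: float


def solve_full_steady_state(Y_e: float, params: Parameters) -> SteadyStateSolution:
    """Solve the closed-form sufficient-resources steady state.

    Parameters
    ----------
    Y_e : external food availability (> 0), in multiples of m_r.
    params : validated parameter set with p1 < p3.

    Raises
    ------
    InfeasibleParametersError
        If the resource-balance denominator is non-positive (recycling
        gains exceed maintenance + division costs, so no finite steady
        state exists).
    """
    validate(params)
    if Y_e <= 0.0:
        raise InfeasibleParametersError(f"Y_e must be positive; got {Y_e}")
    p = params
    phi_bar = p.p1 / p.p3
    mu_i = np.array(p.mu_i, dtype=float)
    turnover = 1.0 - np.exp(-mu_i)
    w = phi_bar * (p.p2 + 2.0 * p.p3) / (p.I * turnover)
    denom = (
        p.m_r * (1.0 + w.sum())
        + p.m_d * (p.p1 + phi_bar * (p.p2 + p.p3))
        - p.gamma * float(np.sum(w * turnover))
    )
    if denom <= 0.0:
        raise InfeasibleParametersError(
            "resource balance has non-positive denominator "
            f"({denom}); recycling exceeds costs, no steady state"
        )
    N_bar = (Y_e * w[0] ** p.delta / denom) ** (1.0 / (1.0 - p.delta))
    D_bar = w * N_bar
    rho_bar = w / w.sum()
    alpha = (1.0 / phi_bar - 1.0) / D_bar
    P_bar = N_bar * phi_bar * (p.p2 + 2.0 * p.p3)
    return SteadyStateSolution(
        phi_bar=phi_bar,
        w=w,
        N_bar=N_bar,
        D_bar=D_bar,
        rho_bar=rho_bar,
        neoblast_fraction=1.0 / (1.0 + float(w.sum())),
        alpha=alpha,
        P_bar=P_bar,
        size_mm=size_from_cells(float(D_bar.sum())),
        Y_e=Y_e,
    )


def make_calibration(ss: SteadyStateSolution, params: Parameters) -> Calibration:
    """Feedback calibration for the food level of ``ss``.

    N_c = sigma_N = c_N * N_bar (default 15 % of the steady neoblast
    number); sigma_D_i and sigma_rho_i are c_D (default 15 %) of the
    steady values of D_i and rho_i.
    """
    return Calibration(
        D_bar=ss.D_bar.copy(),
        rho_bar=ss.rho_bar.copy(),
        alpha=ss.alpha.copy(),
        N_c=params.c_N * ss.N_bar,
        sigma_N=params.c_N * ss.N_bar,
        sigma_D=params.c_D * ss.D_bar,
        sigma_rho=params.c_D * ss.rho_bar,
        Y_e=ss.Y_e,
    )


def size_from_cells(total_differentiated: float, log_base: str = "e") -> float:
    """Planarian size in mm from the total differentiated-cell count.

    ln S = -3.8373 + 0.46582 ln(sum D_i) with natural logarithms by
    default (``log_base="10"`` applies the same coefficients in
    base 10). Neoblasts are excluded: size is determined only by
    differentiated cells.
    """
    if total_differentiated <= 0.0:
        raise ValueError(
            f"total differentiated cells must be positive; got {total_differentiated}"
        )
    if log_base == "e":
        return math.exp(ALLOMETRY_INTERCEPT + ALLOMETRY_SLOPE * math.log(total_differentiated))
    if log_base == "10":
        return 10.0 ** (ALLOMETRY_INTERCEPT + ALLOMETRY_SLOPE * math.log10(total_differentiated))
    raise ValueError(f"log_base must be 'e' or '10'; got {log_base!r}")


def size_food_curve(Y_e_values: Sequence[float], params: Parameters) -> pd.DataFrame:
    """Steady-state size as a function of external food.

    Returns a frame with one row per food level: Y_e, N_bar, D_total,
    size_mm, neoblast_fraction. The curvilinearity comes from only the
    food-gathering class acquiring external resources with exponent
    delta < 1.
    """
    rows = []
    for Y_e in Y_e_values:
        ss = solve_full_steady_state(float(Y_e), params)
        rows.append(
            {
                "Y_e": ss.Y_e,
                "N_bar": ss.N_bar,
                "D_total": float(ss.D_bar.sum()),
                "size_mm": ss.size_mm,
                "neoblast_fraction": ss.neoblast_fraction,
            }
        )
    return pd.DataFrame(rows)


def alpha_vs_food(Y_e_values: Sequence[float], params: Parameters) -> pd.DataFrame:
    """Emergent feedback strengths alpha_i per food level.

    Each alpha_i is strictly decreasing in Y_e; classes with equal
    mortality multipliers share a curve.
    """
    rows = []
    for Y_e in Y_e_values:
        ss = solve_full_steady_state(float(Y_e), params)
        row = {"Y_e": ss.Y_e}
        for i, a in enumerate(ss.alpha, start=1):
            row[f"alpha_{i}"] = float(a)
        rows.append(row)
    return pd.DataFrame(rows)


def _check_roundtrip(ss: SteadyStateSolution) -> float:
    """f_D at the calibrated steady state; equals phi_bar by construction."""
    return f_D(ss.D_bar, ss.alpha)
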