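"""Feedback-control functions and resource thresholds.

All controls are pure, bounded functions of the current state:

* ``f_D(d, alpha)`` — negative feedback from differentiated cells on
  neoblast transitions. The class in shortest supply (largest
  1/(1+alpha_i d_i)) sets the control level.
* ``f_N(n, N_c, sigma_N)`` — positive self-feedback of neoblasts on the
  asymmetric-differentiation transition N -> P,P; a logistic in
  (n - N_c)/sigma_N with f_N(N_c) = 0.5.
* ``f_Q(q, beta_Q)`` — resource-dependent probability that a progeny
  cell completes differentiation rather than apoptosing back to the
  pool: 1 - exp(-beta_Q q).
* ``a_gate(q, lower, mid)`` — Hill-type resource gate shared by the
  three division-class controls a_1, a_2, a_3: zero below its lower
  threshold, 0.5 at the midpoint, asymptoting at 1.
* ``mu_Q(q, thresholds, mu_Q_max)`` — resource-dependent mortality of
  differentiated cells, zero when resources are ample (q > 10 q_mu).

Resources are allocated by priority: maintenance of existing cells
first (threshold q1), then N -> N,N divisions (q2), then N -> N,P (q3),
then N -> P,P (q4). The cumulative thresholds and their midpoints are
computed by :func:`compute_thresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import Parameters

__all__ = [
    "ResourceThresholds",
    "FeedbackValues",
    "compute_thresholds",
    "f_D",
    "f_N",
    "f_Q",
    "a_gate",
    "mu_Q",
    "logistic",
]


def logistic(x: float) -> float:
    """Numerically stable exp(x)/(1+exp(x))."""
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class ResourceThresholds:
    """Cumulative resource requirements of one state, in resource units.

    q1 covers maintenance of all existing cells; q2 additionally covers
    every N -> N,N division; q3 every N -> N,P division; q4 every
    N -> P,P division. q12/q23/q34 are the arithmetic midpoints of
    consecutive thresholds and q_mu = 1.5 q4 anchors resource-dependent
    mortality.
    """

    q1: float
    q2: float
    q3: float
    q4: float
    q12: float
    q23: float
    q34: float
    q_mu: float


@dataclass(frozen=True)
class FeedbackValues:
    """All control values evaluated at one state."""

    fD: float
    fN: float
    fQ: float
    a1: float
    a2: float
    a3: float
    muQ: float


def compute_thresholds(
    n: float,
    d: Sequence[float] | np.ndarray,
    fD: float,
    fN: float,
    params: Parameters,
) -> ResourceThresholds:
    """Cumulative resource thresholds for a state with ``n`` neoblasts
    and differentiated-cell counts ``d``, given the current cell-number
    feedbacks fD and fN.

    q1 = m_r (n + sum d);  q2 = q1 + m_d p1 n;
    q3 = q2 + p2 fD m_d n (the p2 factor counts the N -> N,P divisions;
    set ``params.q3_includes_p2=False`` for the variant without it);
    q4 = q3 + fD fN m_d p3 n;  q_mu = 1.5 q4.
    """
    p = params
    q1 = p.m_r * (n + float(np.sum(d)))
    q2 = q1 + p.m_d * p.p1 * n
    p2_factor = p.p2 if p.q3_includes_p2 else 1.0
    q3 = q2 + p2_factor * fD * p.m_d * n
    q4 = q3 + fD * fN * p.m_d * p.p3 * n
    return ResourceThresholds(
        q1=q1, q2=q2, q3=q3, q4=q4,
        q12=0.5 * (q1 + q2), q23=0.5 * (q2 + q3), q34=0.5 * (q3 + q4),
        q_mu=1.5 * q4,
    )


def f_D(d: Sequence[float] | np.ndarray, alpha: Sequence[float] | np.ndarray) -> float:
    """Feedback from differentiated cells: max_i 1/(1 + alpha_i d_i).

    The max picks the least-inhibited — i.e. scarcest — class, so the
    cells in most demand set the control level. Returns 1 when all
    classes are empty.
    """
    d = np.asarray(d, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if d.shape != alpha.shape:
        raise ValueError(
            f"d and alpha must have the same length; got {d.shape} vs {alpha.shape}"
        )
    return float(np.max(1.0 / (1.0 + alpha * d)))


def f_N(n: float, N_c: float, sigma_N: float) -> float:
    """Neoblast self-feedback: logistic((n - N_c) / sigma_N).

    Strictly increasing in n, with f_N(N_c) = 0.5 exactly. sigma_N sets
    the steepness; both N_c and sigma_N are calibrated as fractions of
    the steady-state neoblast number.
    """
    if sigma_N <= 0.0:
        raise ValueError(f"sigma_N must be positive; got {sigma_N}")
    return logistic((n - N_c) / sigma_N)


def f_Q(q: float, beta_Q: float, *, sufficient_resources: bool = False) -> float:
    """Probability a progeny cell completes differentiation: 1 - exp(-beta_Q q).

    Approximately beta_Q*q for small q; exactly 1 when the model runs in
    sufficient-resources mode.
    """
    if sufficient_resources:
        return 1.0
    if q < 0.0:
        raise ValueError(f"resource level q must be >= 0; got {q}")
    return 1.0 - math.exp(-beta_Q * q)


def a_gate(q: float, lower: float, mid: float, exponent: float = 2.0) -> float:
    """Hill-type resource gate: 0 at/below ``lower``, 0.5 at ``mid``, -> 1.

    a_1, a_2, a_3 are this gate with (q1, q12), (q2, q23), (q3, q34).
    The Hill exponent defaults to 2 but is configurable
    (``Parameters.hill_exponent``).
    """
    if mid <= lower:
        raise ValueError(f"gate midpoint must exceed lower threshold; got lower={lower}, mid={mid}")
    if q <= lower:
        return 0.0
    x = (q - lower) ** exponent
    return x / (x + (mid - lower) ** exponent)


def mu_Q(q: float, thresholds: ResourceThresholds, mu_Q_max: float) -> float:
    """Resource-dependent mortality rate of differentiated cells.

    Zero when resources are ample (q > 10 q_mu) or the ceiling
    mu_Q_max is zero; otherwise
    mu_Q_max (q - q_mu)^2 / ((q - q_mu)^2 + (q1 - q_mu)^2).
    """
    if mu_Q_max == 0.0 or q > 10.0 * thresholds.q_mu:
        return 0.0
    num = (q - thresholds.q_mu) ** 2
    den = num + (thresholds.q1 - thresholds.q_mu) ** 2
    if den == 0.0:  # zero-cell state: every threshold collapses to 0
        return 0.0
    return mu_Q_max * num / den
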