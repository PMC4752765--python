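"""Model parameters: defaults, validation, and flat-config serialization.

The parameter set is the single source of truth for every constant of the
cell-population model:

* ``p1, p2, p3`` — per-step maximum fractions of neoblasts undergoing the
  three division classes (symmetric self-renewal N -> N,N; symmetric
  renewal-plus-progeny N -> N,P; asymmetric differentiation N -> P,P).
  One model step is one unit of model time; "scaled time" used for
  reporting divides the step index by 10,000.
* ``I`` — number of differentiated cell classes (3 in the full model,
  1 in the simplified model).
* ``mu0, s`` — baseline per-step mortality of differentiated cells and
  per-class multipliers, so class i dies at rate mu_i = s_i * mu0.
* ``mu`` — the simplified (single-class) model's constant baseline
  mortality.
* ``m_r, m_d`` — resource cost per cell per step for maintenance, and per
  division. ``gamma``/``gamma_p`` — resources recycled per dying
  differentiated cell / per progeny cell returning to the pool.
* ``delta`` — the surface-area exponent of external food acquisition
  (gain = Y_e * D_1**delta); ``Y_e`` — external food availability in
  multiples of m_r.
* ``beta_Q, mu_Q_max`` — shape of the resource-dependent differentiation
  completion probability f_Q and ceiling of resource-dependent mortality.
* ``c_N, c_D`` — the feedback midpoint/width constants N_c, sigma_N
  (fractions of the steady-state neoblast number) and the mortality
  logistic widths sigma_D, sigma_rho (fractions of the steady values).
* ``sufficient_resources`` — mode flag forcing a_i = 1, f_Q = 1,
  mu_Q = 0, i.e. the resource pool never limits the dynamics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import InvalidParameterError

__all__ = [
    "Parameters",
    "default_parameters",
    "validate",
]


@dataclass(frozen=True)
class Parameters:
    """Complete, immutable parameter set of the model.

    Use :func:`default_parameters` for the standard values;
    :meth:`replace` to derive variants; :func:`validate` to check the
    model invariants.
    """

    # division-class maximum per-step fractions
    p1: float = 0.0001
    p2: float = 0.0005
    p3: float = 0.00015
    # differentiated-cell classes
    I: int = 3
    mu0: float = 0.00015
    s: tuple[float, ...] = (0.75, 1.0, 1.0)
    # simplified-model baseline mortality (unused by the full model)
    mu: float = 0.00015
    # resource economics
    m_r: float = 1.0
    m_d: float = 4.0
    gamma: float = 3.2  # 0.8 * m_d
    gamma_p: float = 3.2
    delta: float = 2.0 / 3.0
    Y_e: float = 450.0
    # resource-dependent feedback shapes
    beta_Q: float = 1e-5
    mu_Q_max: float = 0.0
    hill_exponent: float = 2.0
    # calibration fractions
    c_N: float = 0.15
    c_D: float = 0.15
    # modes / numerical knobs
    sufficient_resources: bool = True
    q3_includes_p2: bool = True
    allocation_floor: float = 1e-9

    def replace(self, **changes: Any) -> "Parameters":
        """Return a copy with the given fields changed (not re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def mu_i(self) -> tuple[float, ...]:
        """Per-class mortality rates mu_i = s_i * mu0."""
        return tuple(si * self.mu0 for si in self.s)

    # -- flat-config round trip ------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["s"] = list(self.s)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Parameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}"
            )
        d = dict(d)
        if "s" in d:
            d["s"] = tuple(float(x) for x in d["s"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Parameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def default_parameters(**overrides: Any) -> Parameters:
    """The standard parameter set.

    Printed model constants: p1=0.0001, p2=0.0005, p3=0.00015, I=3,
    mu0=0.00015, s=(0.75, 1.0, 1.0), m_r=1.0, m_d=4.0, gamma=0.8*m_d=3.2,
    delta=2/3, c_N=c_D=0.15. The remaining constants are package defaults
    (see docs/methods.md): gamma_p=gamma, mu_Q_max=0 (resource-dependent
    death disabled), beta_Q=1e-5, simplified-model mu=mu0.
    """
    return Parameters(**overrides)


def validate(params: Parameters) -> Parameters:
    """Check all parameter invariants; return ``params`` unchanged.

    Raises
    ------
    InvalidParameterError
        If p1 >= p3 (no steady state exists), any rate/cost/fraction is
        non-positive, delta is outside (0, 1), p1+p2+p3 > 1, or the
        per-class multiplier vector ``s`` has length != I.
    """
    p = params
    if not (0.0 < p.p1 < p.p3):
        raise InvalidParameterError(
            f"steady state requires 0 < p1 < p3; got p1={p.p1}, p3={p.p3}"
        )
    if p.p2 <= 0.0:
        raise InvalidParameterError(f"p2 must be positive; got {p.p2}")
    if p.p1 + p.p2 + p.p3 > 1.0:
        raise InvalidParameterError(
            "p1+p2+p3 is the maximum fraction of neoblasts active per step "
            f"and must not exceed 1; got {p.p1 + p.p2 + p.p3}"
        )
    if not isinstance(p.I, int) or p.I < 1:
        raise InvalidParameterError(f"I must be a positive integer; got {p.I}")
    if len(p.s) != p.I:
        raise InvalidParameterError(
            f"s must have length I={p.I}; got length {len(p.s)}"
        )
    for name in ("mu0", "mu", "m_r", "m_d", "gamma", "gamma_p", "Y_e",
                 "beta_Q", "c_N", "c_D", "hill_exponent"):
        v = getattr(p, name)
        if not v > 0.0:
            raise InvalidParameterError(f"{name} must be positive; got {v}")
    for i, si in enumerate(p.s):
        if not si > 0.0:
            raise InvalidParameterError(f"s[{i}] must be positive; got {si}")
    if not (0.0 < p.delta < 1.0):
        raise InvalidParameterError(f"delta must lie in (0, 1); got {p.delta}")
    if p.mu_Q_max < 0.0:
        raise InvalidParameterError(f"mu_Q_max must be >= 0; got {p.mu_Q_max}")
    if not p.allocation_floor > 0.0:
        raise InvalidParameterError(
            f"allocation_floor must be positive; got {p.allocation_floor}"
        )
    return params
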