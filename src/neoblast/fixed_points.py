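"""Fixed points of the one-step maps, found numerically.

The closed-form steady state assumes f_N = 1; with the default
calibration the realized f_N at that point is ~0.9966, so the exact
fixed points of the simulated maps sit elsewhere. Both models in fact
have two interior fixed points under sufficient resources:

* one within ~1-4 % of the closed form — a *saddle*: attracting in all
  directions but one, with a weakly unstable eigenvalue a few 1e-5
  above 1, so trajectories started exactly at the closed form drift
  away over ~1e5 steps;
* a lower *stable* fixed point (the attractor actually reached when an
  animal grows from a small fragment), with all eigenvalues below 1.

:func:`newton_fixed_point` polishes a seed to an exact fixed point of
either map; :func:`simulated_attractor` finds the stable one the way a
grown animal does — by simulating from a small start and polishing.
Dynamics near both points are slow (eigenvalues within a few 1e-4 of
1), so the burn-in matters more than the polish.
"""

from __future__ import annotations

import numpy as np

from .full_model import FullState, step
from .params import Parameters
from .simplified_model import SimpleState, simple_calibration, simple_step, simple_steady_state
from .steady_state import Calibration, make_calibration, solve_full_steady_state

__all__ = ["newton_fixed_point", "simulated_attractor"]


def _map(z: np.ndarray, calib: Calibration, params: Parameters, model: str) -> np.ndarray:
    if model == "simplified":
        nxt, _ = simple_step(SimpleState(0, z[0], z[1], 0.0), calib, params)
        return np.array([nxt.N, nxt.D])
    nxt, _ = step(FullState(0, z[0], z[1:].copy(), 0.0), calib, params)
    return np.concatenate([[nxt.N], nxt.D])


def newton_fixed_point(
    seed: np.ndarray,
    calib: Calibration,
    params: Parameters,
    *,
    model: str = "full",
    tol: float = 1e-13,
    max_iter: int = 50,
) -> np.ndarray:
    """Solve F(z) = z by damped Newton with a finite-difference Jacobian.

    ``seed`` is (N, D_1..D_I) for the full model or (N, D) for the
    simplified one. Converges to the fixed point nearest the seed
    (which may be the saddle — see the module docstring); raises
    RuntimeError if the relative residual does not fall below ``tol``.
    """
    z = np.asarray(seed, dtype=float).copy()
    n = len(z)
    for _ in range(max_iter):
        r = _map(z, calib, params, model) - z
        if np.max(np.abs(r) / z) < tol:
            return z
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-6 * z[j]
            zp = z.copy(); zp[j] += h
            zm = z.copy(); zm[j] -= h
            J[:, j] = (_map(zp, calib, params, model) - _map(zm, calib, params, model)) / (2 * h)
        dz = np.linalg.solve(J - np.eye(n), -r)
        # keep the iterate strictly positive
        scale = 1.0
        while np.any(z + scale * dz <= 0.0):
            scale *= 0.5
        z = z + scale * dz
    r = np.max(np.abs(_map(z, calib, params, model) - z) / z)
    if r < 1e-10:  # converged well enough for any practical purpose
        return z
    raise RuntimeError(f"Newton did not converge (relative residual {r:.2e})")


def simulated_attractor(
    Y_e: float,
    params: Parameters,
    *,
    model: str = "full",
    start_fraction: float = 0.2,
    burn_in: int = 200_000,
    polish: bool = True,
) -> tuple[np.ndarray, Calibration]:
    """The stable fixed point reached by growing from a small animal.

    Simulates ``burn_in`` steps from ``start_fraction`` of the
    closed-form cell numbers (the canonical growth protocol), then
    Newton-polishes the endpoint. Returns (z, calibration) with
    z = (N, D_1..D_I).
    """
    params = params.replace(Y_e=Y_e)
    if model == "simplified":
        ss = simple_steady_state(Y_e, params)
        calib = simple_calibration(Y_e, params)
        z = np.array([start_fraction * ss.N_bar, start_fraction * ss.D_bar])
    elif model == "full":
        sol = solve_full_steady_state(Y_e, params)
        calib = make_calibration(sol, params)
        z = np.concatenate([[start_fraction * sol.N_bar], start_fraction * sol.D_bar])
    else:
        raise ValueError(f"model must be 'full' or 'simplified'; got {model!r}")
    for _ in range(burn_in):
        z = _map(z, calib, params, model)
    if polish:
        z = newton_fixed_point(z, calib, params, model=model)
    return z, calib
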