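"""In-silico experimental protocols.

Four protocols mirror the classical planarian manipulations:

* growth/degrowth/regrowth — start the animal at a fraction of its
  steady-state cell numbers and vary external food over time. On every
  food change the homeostatic targets and feedback constants are
  recalibrated to the new food level (they are food-dependent), so the
  food signal propagates through the feedback system even when
  resources never limit the dynamics.
* fission remodeling — start the full model far from the homeostatic
  cell mix (as in a tail fragment after fission) and watch the
  apoptosis burst that re-balances the composition.
* excision — remove a fraction of differentiated cells from a
  simplified-model animal at steady state (wounding/amputation).
* x-ray — remove a fraction of neoblasts instead (irradiation); body
  size, set by differentiated cells only, is continuous across this
  perturbation.

All protocols are deterministic; identical configurations produce
identical trajectories. Times are reported in scaled units
(steps / 10,000).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .full_model import FullState, simulate
from .params import Parameters, validate
from .simplified_model import (
    SimpleState,
    simple_calibration,
    simple_steady_state,
    simulate_simple,
)
from .steady_state import make_calibration, size_from_cells, solve_full_steady_state
from .trajectory import Trajectory

__all__ = [
    "SCALED_TIME_DIVISOR",
    "scaled_time",
    "steps_from_scaled",
    "FoodSchedule",
    "PerturbationEvent",
    "ExperimentResult",
    "run_growth_experiment",
    "run_fission_experiment",
    "run_excision_experiment",
    "run_xray_experiment",
]

SCALED_TIME_DIVISOR = 10_000


def scaled_time(step: int) -> float:
    """Scaled time of a step index: step / 10,000."""
    if step < 0:
        raise ValueError(f"step must be >= 0; got {step}")
    return step / SCALED_TIME_DIVISOR


def steps_from_scaled(t: float) -> int:
    """Step index of a scaled time (rounded to the nearest step)."""
    return round(t * SCALED_TIME_DIVISOR)


@dataclass(frozen=True)
class FoodSchedule:
    """Piecewise-constant food availability.

    ``points`` is an ordered list of (scaled_time, Y_e) change-points;
    the first entry must be at scaled time 0 and times must be strictly
    increasing.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        pts = tuple((float(t), float(y)) for t, y in self.points)
        object.__setattr__(self, "points", pts)
        if not pts:
            raise ValueError("a food schedule needs at least one change-point")
        if pts[0][0] != 0.0:
            raise ValueError("the first schedule entry must be at scaled time 0")
        times = [t for t, _ in pts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if any(y <= 0.0 for _, y in pts):
            raise ValueError("food levels must be positive")

    @property
    def initial_Y_e(self) -> float:
        return self.points[0][1]

    def changes_as_steps(self) -> dict[int, float]:
        """Later change-points as {step index: Y_e}."""
        return {steps_from_scaled(t): y for t, y in self.points[1:]}


@dataclass(frozen=True)
class PerturbationEvent:
    """A state manipulation applied at one scaled time."""

    scaled_time: float
    kind: str  # excise_differentiated | kill_neoblasts | set_state
    fraction: float | None = None
    state: object | None = None

    def __post_init__(self):
        kinds = ("excise_differentiated", "kill_neoblasts", "set_state")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}; got {self.kind!r}")
        if self.kind in kinds[:2]:
            if self.fraction is None or not (0.0 < self.fraction < 1.0):
                raise ValueError(
                    f"fraction must lie in (0, 1); got {self.fraction}"
                )
        elif self.state is None:
            raise ValueError("set_state requires an explicit state")


@dataclass
class ExperimentResult:
    """Trajectory plus a JSON-serializable summary of one protocol run."""

    trajectory: Trajectory
    summary: dict

    def frame(self) -> pd.DataFrame:
        return self.trajectory.to_frame()

    def write(self, csv_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.trajectory.to_csv(csv_path)
        if summary_path is not None:
            Path(summary_path).write_text(json.dumps(self.summary, indent=2))


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def run_growth_experiment(
    params: Parameters,
    schedule: FoodSchedule,
    start_fraction: float = 0.2,
    *,
    model: str = "full",
    end_scaled_time: float = 21.0,
    record_stride: int = 100,
    recalibrate: bool = True,
    initial_Q: float | None = None,
) -> ExperimentResult:
    """Growth/degrowth/regrowth under a food schedule.

    The animal starts with every compartment at ``start_fraction`` of
    the steady-state cell numbers for the schedule's first food level
    (a "20 % of steady-state size" start is read as 20 % of cell
    numbers; pass a different fraction to change the convention). The
    run ends at ``end_scaled_time``.

    The summary reports, per food epoch, the recalibrated steady-state
    size, the simulated size at the epoch's end, their ratio, and the
    sign of the size change across the epoch.
    """
    validate(params)
    if not (0.0 < start_fraction <= 1.0):
        raise ValueError(f"start_fraction must lie in (0, 1]; got {start_fraction}")
    Y0 = schedule.initial_Y_e
    params = params.replace(Y_e=Y0)
    n_steps = steps_from_scaled(end_scaled_time)

    if model == "full":
        ss = solve_full_steady_state(Y0, params)
        calib = make_calibration(ss, params)
        state0 = FullState(
            t=0, N=start_fraction * ss.N_bar, D=start_fraction * ss.D_bar,
            Q=_default_Q(params, start_fraction * (ss.N_bar + ss.D_bar.sum()), initial_Q),
        )
        traj = simulate(
            state0, calib, params, n_steps,
            food_changes=schedule.changes_as_steps(),
            recalibrate=recalibrate, record_stride=record_stride,
        )
        steady_size = lambda y: solve_full_steady_state(y, params).size_mm
    elif model == "simplified":
        ss = simple_steady_state(Y0, params)
        calib = simple_calibration(Y0, params)
        state0 = SimpleState(
            t=0, N=start_fraction * ss.N_bar, D=start_fraction * ss.D_bar,
            Q=_default_Q(params, start_fraction * (ss.N_bar + ss.D_bar), initial_Q),
        )
        traj = simulate_simple(
            state0, calib, params, n_steps,
            food_changes=schedule.changes_as_steps(),
            recalibrate=recalibrate, record_stride=record_stride,
        )
        steady_size = lambda y: simple_steady_state(y, params).size_mm
    else:
        raise ValueError(f"model must be 'full' or 'simplified'; got {model!r}")

    frame = traj.to_frame()
    epochs = []
    bounds = [t for t, _ in schedule.points] + [end_scaled_time]
    for (t_start, Y_e), t_end in zip(schedule.points, bounds[1:]):
        seg = frame[(frame.scaled_t >= t_start) & (frame.scaled_t <= t_end)]
        s_start = float(seg.size_mm.iloc[0])
        s_end = float(seg.size_mm.iloc[-1])
        target = steady_size(Y_e)
        epochs.append({
            "t_start": t_start, "t_end": t_end, "Y_e": Y_e,
            "steady_size_mm": target,
            "size_start_mm": s_start, "size_end_mm": s_end,
            "size_end_over_steady": s_end / target,
            "direction": "grow" if s_end > s_start else "shrink",
        })
    summary = _jsonable({
        "model": model,
        "start_fraction": start_fraction,
        "schedule": list(schedule.points),
        "epochs": epochs,
    })
    result = ExperimentResult(traj, summary)
    return result


def _default_Q(params: Parameters, total_cells: float, initial_Q: float | None) -> float:
    if initial_Q is not None:
        return initial_Q
    if params.sufficient_resources:
        return 0.0
    # ten steps' worth of maintenance: enough that the gates open at t=0
    return 10.0 * params.m_r * total_cells


def run_fission_experiment(
    params: Parameters,
    Y_e: float = 450.0,
    init_fractions: tuple[float, float, float, float] = (0.5, 0.10, 0.30, 0.05),
    *,
    end_scaled_time: float = 21.0,
    record_stride: int = 100,
    initial_Q: float | None = None,
) -> ExperimentResult:
    """Remodeling after fission (full model, constant food).

    ``init_fractions`` gives the starting neoblast number and the I
    differentiated-class numbers as fractions of their steady values —
    the default (50 %, 10 %, 30 %, 5 %) mimics a fragment whose cell
    mix is far from the homeostatic 40/30/30 distribution. The summary
    reports the apoptosis burst (peak vs terminal death rate) and the
    final class proportions.
    """
    validate(params)
    if len(init_fractions) != params.I + 1:
        raise ValueError(
            f"init_fractions needs 1 + I = {params.I + 1} entries; got {len(init_fractions)}"
        )
    params = params.replace(Y_e=Y_e)
    ss = solve_full_steady_state(Y_e, params)
    calib = make_calibration(ss, params)
    D0 = np.array(init_fractions[1:]) * ss.D_bar
    state0 = FullState(
        t=0, N=init_fractions[0] * ss.N_bar, D=D0,
        Q=_default_Q(params, init_fractions[0] * ss.N_bar + D0.sum(), initial_Q),
    )
    n_steps = steps_from_scaled(end_scaled_time)
    traj = simulate(state0, calib, params, n_steps, record_stride=record_stride)

    frame = traj.to_frame()
    deaths = frame.deaths_total.to_numpy()
    peak_idx = int(np.argmax(deaths))
    terminal = float(deaths[-1])
    D_cols = [f"D_{i}" for i in range(1, params.I + 1)]
    D_final = frame[D_cols].iloc[-1].to_numpy(dtype=float)
    summary = _jsonable({
        "Y_e": Y_e,
        "init_fractions": list(init_fractions),
        "peak_death_rate": float(deaths[peak_idx]),
        "peak_scaled_t": float(frame.scaled_t.iloc[peak_idx]),
        "terminal_death_rate": terminal,
        "burst_ratio": float(deaths[peak_idx]) / terminal if terminal > 0 else math.inf,
        "final_rho": (D_final / D_final.sum()).tolist(),
        "steady_rho": ss.rho_bar.tolist(),
    })
    return ExperimentResult(traj, summary)


def _recovery_times(
    post: pd.DataFrame, pre_values: dict, t_perturb: float, metrics: tuple[str, ...]
) -> dict:
    """Recovery metrics of each column in ``metrics`` after a perturbation.

    For each metric the deviation |x(t) - x_pre| is tracked from the
    perturbation on. Two recovery times (durations, in scaled units)
    are reported:

    * ``within_1pct_of_pre`` — first time the deviation falls within
      1 % of the pre-perturbation value (NaN if the metric never left
      that band, 0 duration being meaningless then);
    * ``deviation_decayed`` — first time at/after the peak deviation at
      which the deviation has decayed below 1 % of that peak. This is
      the scale-free measure: it compares relaxation times between
      metrics whose excursions differ by orders of magnitude.
    """
    out = {}
    t = post.scaled_t.to_numpy()
    for m in metrics:
        x_pre = pre_values[m]
        dev = np.abs(post[m].to_numpy() - x_pre)
        peak_idx = int(np.argmax(dev))
        peak = float(dev[peak_idx])
        # absolute band
        band = 0.01 * abs(x_pre)
        if peak <= band:
            t_abs = float("nan")  # never left the band
        else:
            above = dev > band
            later = np.nonzero(~above & (np.arange(len(dev)) > peak_idx))[0]
            t_abs = float(t[later[0]] - t_perturb) if len(later) else float("inf")
        # deviation-normalized
        decayed = np.nonzero(
            (dev <= 0.01 * peak) & (np.arange(len(dev)) > peak_idx)
        )[0]
        t_dev = float(t[decayed[0]] - t_perturb) if len(decayed) else float("inf")
        out[m] = {
            "pre": float(x_pre),
            "peak_deviation": peak,
            "peak_scaled_t": float(t[peak_idx]),
            "within_1pct_of_pre": t_abs,
            "deviation_decayed": t_dev,
        }
    return out


def _run_perturbation(
    params: Parameters,
    Y_e: float,
    fraction: float,
    t_perturb: float,
    end_scaled_time: float,
    record_stride: int,
    initial_Q: float | None,
    kind: str,
) -> ExperimentResult:
    validate(params)
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1); got {fraction}")
    params = params.replace(Y_e=Y_e)
    # grow the animal to its steady state first: the dynamically reached
    # attractor, not the closed form (which sits next to a saddle of the
    # step map — see neoblast.fixed_points)
    from .fixed_points import simulated_attractor

    z, calib = simulated_attractor(Y_e, params, model="simplified")
    state0 = SimpleState(
        t=0, N=float(z[0]), D=float(z[1]),
        Q=_default_Q(params, float(z.sum()), initial_Q),
    )
    n_pre = steps_from_scaled(t_perturb)
    n_total = steps_from_scaled(end_scaled_time)
    traj = simulate_simple(state0, calib, params, n_pre, record_stride=record_stride)
    pre_state = traj.final_state
    pre_row = traj.to_frame().iloc[-1]
    if kind == "excise_differentiated":
        perturbed = SimpleState(
            t=pre_state.t, N=pre_state.N, D=(1.0 - fraction) * pre_state.D, Q=pre_state.Q
        )
    else:  # kill_neoblasts
        perturbed = SimpleState(
            t=pre_state.t, N=(1.0 - fraction) * pre_state.N, D=pre_state.D, Q=pre_state.Q
        )
    post_traj = simulate_simple(
        perturbed, traj.final_calib, traj.final_params,
        n_total - n_pre, record_stride=record_stride,
    )
    post_frame = post_traj.to_frame()
    traj.extend(post_traj)
    traj.final_state = post_traj.final_state
    traj.final_calib = post_traj.final_calib
    traj.final_params = post_traj.final_params

    metrics = ("size_mm", "fD", "fN", "neoblast_fraction")
    pre_values = {m: float(pre_row[m]) for m in metrics}
    post_row = post_frame.iloc[0]
    summary = _jsonable({
        "kind": kind,
        "Y_e": Y_e,
        "fraction": fraction,
        "t_perturb": t_perturb,
        "pre": pre_values,
        "post": {m: float(post_row[m]) for m in metrics},
        "final": {m: float(post_frame.iloc[-1][m]) for m in metrics},
        "recovery": _recovery_times(post_frame, pre_values, t_perturb, metrics),
    })
    return ExperimentResult(traj, summary)


def run_excision_experiment(
    params: Parameters,
    Y_e: float = 240.0,
    fraction: float = 0.25,
    t_perturb: float = 7.0,
    *,
    end_scaled_time: float = 21.0,
    record_stride: int = 100,
    initial_Q: float | None = None,
) -> ExperimentResult:
    """Excision/wounding: remove ``fraction`` of the differentiated
    cells of a steady-state simplified-model animal at ``t_perturb``.

    Size drops discontinuously; the differentiated-cell feedback f_D
    jumps up (fewer inhibiting cells) and relaxes back quickly, while
    the neoblast self-feedback f_N dips only slightly but relaxes far
    more slowly. The summary records before/after values and the
    recovery times of size, f_D, f_N, and the neoblast fraction.
    """
    return _run_perturbation(
        params, Y_e, fraction, t_perturb, end_scaled_time,
        record_stride, initial_Q, "excise_differentiated",
    )


def run_xray_experiment(
    params: Parameters,
    Y_e: float = 240.0,
    fraction: float = 0.25,
    t_perturb: float = 7.0,
    *,
    end_scaled_time: float = 21.0,
    record_stride: int = 100,
    initial_Q: float | None = None,
) -> ExperimentResult:
    """Irradiation: remove ``fraction`` of the neoblasts at ``t_perturb``.

    Size — set by differentiated cells only — is exactly continuous at
    the perturbation; f_N drops sharply and then recovers while f_D
    rises transiently as the differentiated pool decays.
    """
    return _run_perturbation(
        params, Y_e, fraction, t_perturb, end_scaled_time,
        record_stride, initial_Q, "kill_neoblasts",
    )
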