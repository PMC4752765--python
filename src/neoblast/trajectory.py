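"""Time-indexed simulation records and their CSV schema.

A trajectory row holds the state at one recorded step plus the
per-step diagnostics of the transition leaving that state: feedback
values, progeny production, mortality rates and deaths, the partition
of non-resource mortality between level- and proportion-imbalance,
body size, and the food level in force.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["Trajectory", "trajectory_columns", "column_descriptions"]

CSV_FLOAT_FORMAT = "%.12g"  # 12 significant digits: stable yet precise


def trajectory_columns(I: int) -> list[str]:
    """Ordered CSV columns for a model with I differentiated classes."""
    cols = ["t", "scaled_t", "N"]
    cols += [f"D_{i}" for i in range(1, I + 1)]
    cols += ["Q", "size_mm", "neoblast_fraction",
             "fD", "fN", "fQ", "a1", "a2", "a3", "P_total"]
    cols += [f"M_{i}" for i in range(1, I + 1)]
    cols += ["deaths_total"]
    cols += [f"level_share_{i}" for i in range(1, I + 1)]
    cols += [f"proportion_share_{i}" for i in range(1, I + 1)]
    cols += ["Y_e"]
    return cols


def column_descriptions(I: int) -> dict[str, str]:
    desc = {
        "t": "step index (one step = one unit of model time)",
        "scaled_t": "t / 10000, the time unit used for reporting",
        "N": "neoblast count",
        "Q": "resource-pool level (constant in sufficient-resources mode)",
        "size_mm": "body size from the differentiated-cell allometry",
        "neoblast_fraction": "N / (N + sum_i D_i)",
        "fD": "feedback from differentiated cells, max_i 1/(1+alpha_i D_i)",
        "fN": "neoblast self-feedback logistic((N-N_c)/sigma_N)",
        "fQ": "progeny differentiation-completion probability",
        "a1": "resource gate on N->N,N divisions",
        "a2": "resource gate on N->N,P divisions",
        "a3": "resource gate on N->P,P divisions",
        "P_total": "progeny produced this step",
        "deaths_total": "differentiated cells dying this step, all classes",
        "Y_e": "external food availability in force at this step",
    }
    for i in range(1, I + 1):
        desc[f"D_{i}"] = f"count of differentiated cells of class {i}"
        desc[f"M_{i}"] = f"per-step mortality rate of class {i}"
        desc[f"level_share_{i}"] = (
            f"share of class-{i} non-resource mortality attributed to "
            "deviation of the cell number from its homeostatic level"
        )
        desc[f"proportion_share_{i}"] = (
            f"share of class-{i} non-resource mortality attributed to "
            "deviation of the class proportion from its homeostatic value"
        )
    return desc


class Trajectory:
    """Recorded states + diagnostics of one simulation run."""

    def __init__(self, I: int):
        self.I = I
        self._rows: list[dict] = []

    def append(self, row: dict) -> None:
        self._rows.append(row)

    def extend(self, other: "Trajectory") -> None:
        if other.I != self.I:
            raise ValueError("cannot concatenate trajectories with different I")
        self._rows.extend(other._rows)

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=trajectory_columns(self.I))

    def to_csv(self, path: str | Path, *, write_schema: bool = True) -> None:
        """Write the trajectory CSV (12 significant digits) and, by
        default, a JSON schema documenting every column next to it."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
        if write_schema:
            schema = {
                "columns": [
                    {"name": c, "description": column_descriptions(self.I)[c]}
                    for c in trajectory_columns(self.I)
                ]
            }
            path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))
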