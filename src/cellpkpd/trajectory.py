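"""Trajectory container shared by the cell-level and whole-body simulators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .units import MINUTES_PER_DAY


@dataclass
class Trajectory:
    """Time grid plus named state variables of one simulated scenario.

    ``t`` is in canonical minutes and strictly increasing; ``states`` maps a
    variable name to its value on the grid; ``units`` records the unit of
    each variable; ``metadata`` carries scenario provenance (dose, fixture
    id, solver tolerances, derived constants such as the pretreatment
    steady state) sufficient to regenerate the run.
    """

    t: np.ndarray
    states: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("time grid must be a 1-d array with >= 2 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")
        for name, values in self.states.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.t.shape:
                raise ValueError(f"state {name!r} does not match the time grid")
            self.states[name] = values

    @property
    def t_days(self) -> np.ndarray:
        return self.t / MINUTES_PER_DAY

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[name]

    def __contains__(self, name: str) -> bool:
        return name in self.states

    def to_frame(self, long: bool = True) -> pd.DataFrame:
        """Export as a DataFrame (long format: time, variable, value, unit)."""
        if not long:
            wide = pd.DataFrame({"time_min": self.t, **self.states})
            return wide
        rows = []
        for name, values in self.states.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.t,
                        "variable": name,
                        "value": values,
                        "unit": self.units.get(name, ""),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path, long: bool = True) -> None:
        self.to_frame(long=long).to_csv(path, index=False)


def output_grid(
    t_end_min: float,
    n_log: int = 400,
    t_first_min: float = 1.0,
    daily: bool = True,
) -> np.ndarray:
    """Dense logarithmic early grid plus daily points, starting at t = 0.

    The binding transient is over within minutes to hours while the PK tail
    stretches over weeks, so a geometric grid resolves both; daily points
    keep late-time effect integrals well sampled.
    """
    if t_end_min <= 0:
        raise ValueError("t_end_min must be > 0")
    pieces = [np.array([0.0]), np.geomspace(t_first_min, t_end_min, n_log)]
    if daily and t_end_min > MINUTES_PER_DAY:
        pieces.append(np.arange(MINUTES_PER_DAY, t_end_min, MINUTES_PER_DAY))
    grid = np.unique(np.concatenate(pieces))
    return grid[grid <= t_end_min]
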