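"""Objective functions.

Two objectives are supported:

* the *ideal oscillator* target — a candidate is rewarded for any one of
  its species swinging between two reference concentrations C1 (at every
  half period T/2, 3T/2, ...) and C2 (at every full period T, 2T, ...)
  over 5.5 imposed periods; and
* matching an arbitrary observed time series column-by-column.

Both score as the reciprocal of a summed absolute deviation, so larger is
better; an unsimulable candidate scores exactly 0.0 and a perfect match is
capped (the reciprocal is singular at zero deviation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ReactionNetwork
from .simulation import DEFAULT_ATOL, DEFAULT_RTOL, simulate

__all__ = [
    "OscillatorTarget",
    "TimeSeriesTarget",
    "target_points",
    "oscillator_fitness",
    "timeseries_fitness",
]

#: Deviations below this floor are treated as a perfect match ...
DEVIATION_FLOOR = 1e-9
#: ... capping fitness at its reciprocal instead of overflowing.
FITNESS_CAP = 1e9


@dataclass(frozen=True)
class OscillatorTarget:
    """Imposed oscillation: period ``period``, references ``c1``/``c2``.

    Checkpoints sit at every half period up to ``n_periods`` (5.5 periods
    -> 11 checkpoints), alternating c1 (half periods) and c2 (full periods).
    """

    period: float = 1.0
    c1: float = 10.0
    c2: float = 2.0
    n_periods: float = 5.5

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError("period must be positive")
        if self.c1 == self.c2:
            raise ValueError("c1 and c2 must differ")
        if not self.n_periods > 0:
            raise ValueError("n_periods must be positive")


def target_points(t: OscillatorTarget) -> tuple[np.ndarray, np.ndarray]:
    """Checkpoint times and ideal values for an oscillator target."""
    n = int(round(2 * t.n_periods))
    times = t.period / 2.0 * np.arange(1, n + 1)
    ideal = np.where(np.arange(1, n + 1) % 2 == 1, t.c1, t.c2)
    return times, ideal.astype(float)


@dataclass(frozen=True)
class TimeSeriesTarget:
    """Observed concentrations on a strictly increasing time grid."""

    times: tuple[float, ...]
    observed: tuple[tuple[float, ...], ...]  # row per time, column per species

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        observed = tuple(tuple(float(v) for v in row) for row in self.observed)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "observed", observed)
        if len(observed) != len(times):
            raise ValueError("one observation row per time point required")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.observed, dtype=float)

    @classmethod
    def from_csv(cls, path) -> "TimeSeriesTarget":
        """Read a delimited table with header ``time,S0,S1,...``."""
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError("time-series file needs a 'time' column")
        times = df["time"].to_numpy(dtype=float)
        obs = df.drop(columns="time").to_numpy(dtype=float)
        return cls(times=tuple(times), observed=tuple(map(tuple, obs)))

    def to_csv(self, path, species_names=None) -> None:
        mat = self.matrix
        names = species_names or [f"S{i}" for i in range(mat.shape[1])]
        df = pd.DataFrame(mat, columns=list(names))
        df.insert(0, "time", self.times)
        df.to_csv(Path(path), index=False)


def _reciprocal_score(deviation: float) -> float:
    if deviation <= DEVIATION_FLOOR:
        return FITNESS_CAP
    return min(1.0 / deviation, FITNESS_CAP)


def oscillator_fitness(
    net: ReactionNetwork,
    target: OscillatorTarget = OscillatorTarget(),
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Score a candidate against the ideal-oscillator checkpoints.

    The candidate is simulated over [0, n_periods*T]; for each species s the
    deviation D_s sums |ideal - candidate_s| over the checkpoints, and the
    fitness is max_s 1/D_s — the single best-matching species counts.
    Simulation failure scores 0.0.
    """
    times, ideal = target_points(target)
    traj = simulate(net, t_end=times[-1], t_eval=times, rtol=rtol, atol=atol)
    if not traj.success:
        return 0.0
    deviations = np.sum(np.abs(traj.concentrations - ideal[:, None]), axis=0)
    return float(max(_reciprocal_score(d) for d in deviations))


def timeseries_fitness(
    net: ReactionNetwork,
    target: TimeSeriesTarget,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Score a candidate against observed data, summed over all species.

    Column i of the observations corresponds to species i of the network
    (no permutation matching). Same failure/cap rules as the oscillator
    objective.
    """
    obs = target.matrix
    if obs.shape[1] != len(net.species):
        raise ValueError("observed column count must equal the species count")
    times = np.asarray(target.times, dtype=float)
    traj = simulate(net, t_end=times[-1], t_eval=times, rtol=rtol, atol=atol)
    if not traj.success:
        return 0.0
    deviation = float(np.sum(np.abs(traj.concentrations - obs)))
    return _reciprocal_score(deviation)
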