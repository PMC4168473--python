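"""Raw sweep handling: interpolation onto an equidistant temperature grid and
per-subject/per-layer averaging into representative curves.

Every downstream feature extractor consumes :class:`RepresentativeCurve`
objects produced here.  Temperatures are absolute degrees Celsius; "relative
degrees" measure from the grid start (grid[0] == relative 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorSweep",
    "RepresentativeCurve",
    "temperature_grid",
    "interpolate_sweep",
    "average_sweeps",
    "representative_curves",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "read_curves_csv",
    "write_curves_csv",
]

SWEEP_COLUMNS = ["subject_id", "group", "sweep", "layer", "temperature_c", "conductance"]
CURVE_COLUMNS = ["subject_id", "group", "layer", "temperature_c", "conductance"]


@dataclass
class SensorSweep:
    """One conductance-vs-heater-temperature recording.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    group : str
        Binary class label.
    sweep : int
        Sweep number within the subject's session (1-based).
    layer : int
        Sensor layer (1-based).
    temperatures : ndarray
        Strictly increasing heater temperatures, degrees Celsius.
    conductance : ndarray
        Sensor response at each temperature, arbitrary units.
    """

    subject_id: str
    group: str
    sweep: int
    layer: int
    temperatures: np.ndarray
    conductance: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.conductance = np.asarray(self.conductance, dtype=float)
        if self.temperatures.ndim != 1 or self.conductance.ndim != 1:
            raise ValueError("samples: temperatures and conductance must be 1-D")
        if self.temperatures.size != self.conductance.size:
            raise ValueError("samples: temperatures and conductance differ in length")
        if self.temperatures.size < 2:
            raise ValueError("samples: a sweep needs at least 2 samples")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("samples: temperatures must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.temperatures.size


@dataclass
class RepresentativeCurve:
    """Per-subject, per-layer averaged curve on an equidistant grid."""

    subject_id: str
    layer: int
    grid: np.ndarray
    values: np.ndarray
    n_sweeps_averaged: int
    group: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.size != self.values.size:
            raise ValueError("grid and values differ in length")
        steps = np.diff(self.grid)
        if steps.size and not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("grid spacing must be constant")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def span(self) -> float:
        """Temperature span in degrees (grid end minus grid start)."""
        return float(self.grid[-1] - self.grid[0])

    @property
    def relative(self) -> np.ndarray:
        """Grid in relative degrees (0 at the low-temperature end)."""
        return self.grid - self.grid[0]


def temperature_grid(start_c: float = 195.0, end_c: float = 355.0, step_c: float = 1.0) -> np.ndarray:
    """Equidistant grid spanning ``[start_c, end_c]`` inclusive."""
    if end_c <= start_c:
        raise ValueError("temp_end_c: must exceed temp_start_c")
    if step_c <= 0:
        raise ValueError("temp_step_c: must be positive")
    n = round((end_c - start_c) / step_c)
    if not np.isclose(start_c + n * step_c, end_c, rtol=0, atol=1e-9):
        raise ValueError("temp_step_c: step must divide the span")
    return start_c + step_c * np.arange(n + 1)


def interpolate_sweep(sweep: SensorSweep, grid: np.ndarray) -> np.ndarray:
    """Linearly interpolate one sweep at each grid temperature.

    The grid must lie inside the sweep's sampled temperature range; no
    extrapolation is performed.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = sweep.temperatures[0], sweep.temperatures[-1]
    if grid[0] < lo - 1e-12:
        raise ValueError(
            f"grid start {grid[0]:g} below sampled range start {lo:g} (no extrapolation)"
        )
    if grid[-1] > hi + 1e-12:
        raise ValueError(
            f"grid end {grid[-1]:g} above sampled range end {hi:g} (no extrapolation)"
        )
    return np.interp(grid, sweep.temperatures, sweep.conductance)


def average_sweeps(sweeps: Sequence[SensorSweep], grid: np.ndarray) -> RepresentativeCurve:
    """Pointwise mean of the interpolated sweeps of one subject and layer."""
    sweeps = list(sweeps)
    if not sweeps:
        raise ValueError("average_sweeps requires at least one sweep")
    keys = {(s.subject_id, s.layer) for s in sweeps}
    if len(keys) > 1:
        raise ValueError(f"sweeps mix subject/layer keys: {sorted(keys)}")
    stacked = np.vstack([interpolate_sweep(s, grid) for s in sweeps])
    first = sweeps[0]
    return RepresentativeCurve(
        subject_id=first.subject_id,
        layer=first.layer,
        grid=np.asarray(grid, dtype=float),
        values=stacked.mean(axis=0),
        n_sweeps_averaged=len(sweeps),
        group=first.group,
    )


def representative_curves(
    sweeps: Iterable[SensorSweep], grid: np.ndarray
) -> list[RepresentativeCurve]:
    """Group sweeps by (subject, layer) and average each group.

    Output order follows first appearance of each (subject, layer) key, so a
    cohort generated subject-by-subject keeps its ordering.
    """
    buckets: dict[tuple[str, int], list[SensorSweep]] = {}
    for s in sweeps:
        buckets.setdefault((s.subject_id, s.layer), []).append(s)
    return [average_sweeps(group, grid) for group in buckets.values()]


# ---------------------------------------------------------------------------
# CSV schema (long format, one row per sample)

def sweeps_to_frame(sweeps: Iterable[SensorSweep]) -> pd.DataFrame:
    rows = []
    for s in sweeps:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "sweep": s.sweep,
                    "layer": s.layer,
                    "temperature_c": s.temperatures,
                    "conductance": s.conductance,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=SWEEP_COLUMNS)
    return pd.concat(rows, ignore_index=True)[SWEEP_COLUMNS]


def frame_to_sweeps(df: pd.DataFrame) -> list[SensorSweep]:
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sweep table missing columns: {missing}")
    out = []
    for (sid, group, sweep, layer), sub in df.groupby(
        ["subject_id", "group", "sweep", "layer"], sort=False
    ):
        out.append(
            SensorSweep(
                subject_id=str(sid),
                group=str(group),
                sweep=int(sweep),
                layer=int(layer),
                temperatures=sub["temperature_c"].to_numpy(float),
                conductance=sub["conductance"].to_numpy(float),
            )
        )
    return out


def write_sweeps_csv(sweeps: Iterable[SensorSweep], path) -> None:
    sweeps_to_frame(sweeps).to_csv(path, index=False)


def read_sweeps_csv(path) -> list[SensorSweep]:
    # round_trip parsing keeps write->read bit-exact
    return frame_to_sweeps(pd.read_csv(path, float_precision="round_trip"))


def write_curves_csv(curves: Iterable[RepresentativeCurve], path) -> None:
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": c.subject_id,
                    "group": "" if c.group is None else c.group,
                    "layer": c.layer,
                    "temperature_c": c.grid,
                    "conductance": c.values,
                }
            )
        )
    frame = (
        pd.concat(rows, ignore_index=True)[CURVE_COLUMNS]
        if rows
        else pd.DataFrame(columns=CURVE_COLUMNS)
    )
    frame.to_csv(path, index=False)


def read_curves_csv(path) -> list[RepresentativeCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (sid, layer), sub in df.groupby(["subject_id", "layer"], sort=False):
        group = sub["group"].iloc[0] if "group" in sub.columns else None
        if pd.isna(group):
            group = None
        out.append(
            RepresentativeCurve(
                subject_id=str(sid),
                layer=int(layer),
                grid=sub["temperature_c"].to_numpy(float),
                values=sub["conductance"].to_numpy(float),
                n_sweeps_averaged=0,
                group=None if group is None else str(group),
            )
        )
    return out
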