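"""Synthetic single-cell glucose-shift datasets.

The original microscopy series are not deposited, so every downstream
stage is exercised on generated data with the statistical structure the
analysis assumes: ~46-56 cells per dataset, at most 15 observations per
cell spanning -30 s to 1200 s, log-normal cell parameters (M_s, k2, k4)
with a full 3x3 covariance on the log scale, additive Gaussian measurement
noise, and an occasional near-empty cell (1-2 observations) that
reproduces the failure mode of naive per-cell fitting.

The default sampling schedule is front-loaded to resolve the fast nuclear
exit; the real per-cell sampling times are not published, so the schedule
is a configurable stand-in with the published count of 15 points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from . import _kernels
from .model import GlucoseProgram

if TYPE_CHECKING:  # pragma: no cover
    from .foce import PopulationParameters

__all__ = [
    "DEFAULT_SCHEDULE",
    "CellTimeSeries",
    "StudyDesign",
    "Dataset",
    "default_design",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

#: 15 sampling times (s), denser before 300 s where the exit happens.
DEFAULT_SCHEDULE = (
    -30.0, 0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0,
    300.0, 420.0, 540.0, 720.0, 900.0, 1080.0, 1200.0,
)

_TABLE_OF_EXPERIMENTS = {1: (56, 1.5), 2: (46, 1.5), 3: (46, 1.0), 4: (46, 0.5)}


@dataclass(frozen=True)
class CellTimeSeries:
    """One cell's sparse observation times (s) and intensities (a.u.)."""

    cell_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "intensities", np.asarray(self.intensities, dtype=float)
        )
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be sorted strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class StudyDesign:
    """Sampling design for one synthetic dataset.

    `sampling_times` holds one (possibly ragged) schedule per cell;
    `fraction_sparse` is the proportion of cells reduced to 1-2 random
    observations, emulating the rare near-empty series in the real data.
    """

    n_cells: int
    sampling_times: List[np.ndarray]
    program: GlucoseProgram
    fraction_sparse: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if len(self.sampling_times) != self.n_cells:
            raise ValueError("need one sampling schedule per cell")
        coerced = []
        for sched in self.sampling_times:
            arr = np.asarray(sched, dtype=float)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise ValueError("each schedule must be non-empty and sorted")
            coerced.append(arr)
        self.sampling_times = coerced
        if not 0.0 <= self.fraction_sparse < 1.0:
            raise ValueError("fraction_sparse must be in [0, 1)")

    @classmethod
    def uniform(
        cls,
        n_cells: int,
        program: GlucoseProgram,
        schedule: Sequence[float] = DEFAULT_SCHEDULE,
        fraction_sparse: float = 0.05,
    ) -> "StudyDesign":
        sched = np.asarray(schedule, dtype=float)
        return cls(n_cells, [sched.copy() for _ in range(n_cells)], program,
                   fraction_sparse)


@dataclass
class Dataset:
    """A collection of cells sharing one glucose program.

    For synthetic data the generating population parameters and the true
    per-cell random effects are retained for recovery tests.
    """

    cells: List[CellTimeSeries]
    program: GlucoseProgram
    true_parameters: Optional["PopulationParameters"] = None
    true_etas: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.cells)

    def n_observations(self) -> int:
        return int(sum(len(c) for c in self.cells))

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"cell_id": c.cell_id, "time_s": c.times, "intensity": c.intensities}
            )
            for c in self.cells
        ]
        return pd.concat(frames, ignore_index=True)


def default_design(experiment: int, fraction_sparse: float = 0.05) -> StudyDesign:
    """Design emulating one of the four published experiments (1-4)."""
    if experiment not in _TABLE_OF_EXPERIMENTS:
        raise ValueError(f"unknown experiment id: {experiment!r} (expected 1-4)")
    n_cells, g = _TABLE_OF_EXPERIMENTS[experiment]
    program = GlucoseProgram(post_level=g)
    return StudyDesign.uniform(n_cells, program, fraction_sparse=fraction_sparse)


def generate_dataset(
    theta_true: "PopulationParameters",
    design: StudyDesign,
    seed: Optional[int] = None,
) -> Dataset:
    """Draw one synthetic dataset from the population model.

    Per cell: draw eta ~ N(0, Omega) as U z with z standard normal (so a
    zero factor degenerates cleanly to the median cell), form the
    individual parameters, simulate the noise-free trajectory and add
    observation noise of variance s.  Deterministic given `seed`; the true
    eta draws are retained on the returned dataset.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(theta_true.omega, dtype=float)
    u = np.array([[w[0], w[1], w[2]], [0.0, w[3], w[4]], [0.0, 0.0, w[5]]])
    n = design.n_cells
    etas = rng.standard_normal((n, 3)) @ u.T

    # which cells are near-empty, and how many points they keep
    n_sparse = int(round(design.fraction_sparse * n))
    sparse_ids = rng.choice(n, size=n_sparse, replace=False) if n_sparse else []
    sparse_counts = {int(i): int(rng.integers(1, 3)) for i in sparse_ids}

    shift = design.program.shift_time
    ratio = design.program.ratio
    sd = np.sqrt(theta_true.s)
    width = len(str(n))
    cells = []
    for i in range(n):
        times = design.sampling_times[i]
        if i in sparse_counts:
            keep = np.sort(rng.choice(times.size, size=sparse_counts[i], replace=False))
            times = times[keep]
        ms = theta_true.Mbar_s * np.exp(etas[i, 0])
        k2 = theta_true.kbar2 * np.exp(etas[i, 1])
        k4 = theta_true.kbar4 * np.exp(etas[i, 2])
        pred = _kernels.mig1_pred(times - shift, ms, k2, k4, ratio)
        y = pred + (rng.normal(0.0, sd, size=pred.shape) if theta_true.s > 0 else 0.0)
        cells.append(CellTimeSeries(f"cell_{i:0{width}d}", times, y))
    return Dataset(
        cells=cells,
        program=design.program,
        true_parameters=theta_true,
        true_etas=etas,
        seed=seed if seed is None or isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# long-format CSV + JSON sidecar I/O


def write_dataset(dataset: Dataset, csv_path) -> Path:
    """Write long-format CSV (cell_id, time_s, intensity) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    dataset.to_frame().to_csv(csv_path, index=False)
    meta = {
        "glucose_program": {
            "pre_level": dataset.program.pre_level,
            "post_level": dataset.program.post_level,
            "shift_time": dataset.program.shift_time,
            "start_time": dataset.program.start_time,
        },
        "seed": dataset.seed,
        "n_cells": len(dataset),
    }
    if dataset.true_parameters is not None:
        theta = dataset.true_parameters
        meta["true_parameters"] = {
            "Mbar_s": theta.Mbar_s, "kbar2": theta.kbar2, "kbar4": theta.kbar4,
            "s": theta.s, "omega": list(theta.omega),
        }
    if dataset.true_etas is not None:
        meta["true_etas"] = np.asarray(dataset.true_etas).tolist()
    sidecar = csv_path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_dataset(csv_path) -> Dataset:
    """Read a long-format CSV (+ optional sidecar), validating per-cell sorting."""
    from .foce import PopulationParameters

    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    required = {"cell_id", "time_s", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset CSV must have columns {sorted(required)}")

    sidecar = csv_path.with_suffix(".meta.json")
    program = GlucoseProgram(post_level=1.0)
    theta = None
    etas = None
    seed = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        program = GlucoseProgram(**meta["glucose_program"])
        if "true_parameters" in meta:
            tp = meta["true_parameters"]
            theta = PopulationParameters(
                tp["Mbar_s"], tp["kbar2"], tp["kbar4"], tp["s"], tuple(tp["omega"])
            )
        if "true_etas" in meta:
            etas = np.asarray(meta["true_etas"], dtype=float)
        seed = meta.get("seed")

    cells = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        cells.append(
            CellTimeSeries(
                str(cell_id),
                group["time_s"].to_numpy(),
                group["intensity"].to_numpy(),
            )
        )
    return Dataset(cells, program, theta, etas, seed)
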