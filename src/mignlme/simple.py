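"""Non-model-based extraction of response metrics from observed series.

The simple analysis reads the response characteristics directly off each
cell's data points: the amplitude is the maximal drop below the baseline,
the response time is the time of the maximizing point, and the duration is
the time between the first data point below the 50%-amplitude level and
the first subsequent point back above it.  Optionally the series is first
smoothed with a cubic B-spline and resampled at 1000 equidistant times.

The baseline is taken as the mean of all observations at t <= 0 (falling
back to the first observation when no pre-shift points exist); response
time ties break to the earliest time.  Both choices are conventions of
this implementation -- the procedure is otherwise parameter-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

from .data import CellTimeSeries
from .predict import METRICS

__all__ = ["SimpleMetrics", "SmoothedSeries", "raw_metrics", "smooth_resample",
           "population_medians"]


@dataclass(frozen=True)
class SimpleMetrics:
    """Per-cell metrics; missing pieces are NaN with an explanatory flag."""

    cell_id: str
    response_time: float
    amplitude: float
    duration: float
    baseline: float
    no_response: bool = False   # non-positive amplitude
    partial: bool = False       # insufficient points for full metrics


@dataclass(frozen=True)
class SmoothedSeries:
    """1000 equidistant samples of a cubic B-spline fit over the observed span."""

    cell_id: str
    times: np.ndarray
    values: np.ndarray

    def as_cell(self) -> CellTimeSeries:
        return CellTimeSeries(self.cell_id, self.times, self.values)


def raw_metrics(cell: CellTimeSeries, shift_time: float = 0.0) -> SimpleMetrics:
    """Read the three response characteristics directly off the data points."""
    t = cell.times - shift_time
    y = cell.intensities
    pre = t <= 0.0
    baseline = float(y[pre].mean()) if pre.any() else float(y[0])
    post = t > 0.0
    tp, yp = t[post], y[post]
    partial = not pre.any() or post.sum() < 2
    if tp.size == 0:
        return SimpleMetrics(cell.cell_id, np.nan, np.nan, np.nan, baseline,
                             partial=True)

    drops = baseline - yp
    i_max = int(np.argmax(drops))          # ties -> earliest time
    max_drop = float(drops[i_max])
    if max_drop <= 0.0 or baseline <= 0.0:
        return SimpleMetrics(cell.cell_id, np.nan, 100.0 * max_drop / baseline,
                             np.nan, baseline, no_response=True, partial=partial)
    amplitude = 100.0 * max_drop / baseline
    response_time = float(tp[i_max])

    level = baseline - 0.5 * max_drop
    below = np.flatnonzero(yp < level)
    duration = np.nan
    if below.size:
        first_below = int(below[0])
        above_after = np.flatnonzero(yp[first_below:] >= level)
        if above_after.size:
            duration = float(tp[first_below + above_after[0]] - tp[first_below])
    if not np.isfinite(duration):
        partial = True
    return SimpleMetrics(cell.cell_id, response_time, amplitude, duration,
                         baseline, partial=partial)


def smooth_resample(
    cell: CellTimeSeries,
    mode: str = "gcv",
    n_points: int = 1000,
) -> SmoothedSeries:
    """Cubic B-spline fit evaluated at `n_points` equidistant times.

    `mode="gcv"` uses a smoothing spline with the penalty chosen by
    generalized cross-validation; `mode="interpolate"` forces exact
    interpolation.  Needs at least 4 observations (cubic pieces).
    """
    t = cell.times
    y = cell.intensities
    if t.size < 4:
        raise ValueError("cubic spline smoothing needs at least 4 observations")
    if mode == "gcv":
        spline = make_smoothing_spline(t, y)
    elif mode == "interpolate":
        spline = make_interp_spline(t, y, k=3)
    else:
        raise ValueError(f"unknown mode {mode!r} (use 'gcv' or 'interpolate')")
    grid = np.linspace(t[0], t[-1], n_points)
    return SmoothedSeries(cell.cell_id, grid, np.asarray(spline(grid), dtype=float))


def population_medians(metrics: Iterable[SimpleMetrics]) -> dict:
    """Empirical medians of the per-cell metrics, with exclusion counts.

    A cell contributes to each metric's median only where that metric is
    finite; the counts of flagged (no-response / partial) cells are
    reported alongside.
    """
    metrics = list(metrics)
    out: Dict[str, Optional[float]] = {}
    for name in METRICS:
        vals = np.array([getattr(m, name) for m in metrics], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[name] = float(np.median(vals)) if vals.size else None
        out[f"n_{name}"] = int(vals.size)
    out["n_cells"] = len(metrics)
    out["n_no_response"] = int(sum(m.no_response for m in metrics))
    out["n_partial"] = int(sum(m.partial for m in metrics))
    return out
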