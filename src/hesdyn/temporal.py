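"""Per-cell temporal switching statistics.

Single-cell traces are smoothed (order-1 Savitzky-Golay, 165-min frame) so
that brief noise excursions do not register as state changes, then
segmented into *high* runs (strictly above a threshold) and *low* runs (at
or below it).  The threshold is relative -- the population mean expression
of the simulation over the analysis window -- because coupling strength
shifts the absolute expression level.  From the run durations
("persistence times" T_up,n / T_down,n) come:

* alpha_up / alpha_down -- fractions of the measurement time spent high/low;
* the dynamicity coefficient ``Dc = 2 min(alpha_up, alpha_down)``: 0 for a
  stationary trace, 1 for balanced switching;
* mean persistence times (their sum is the period of a regular switcher).

Runs truncated by the window edges are kept at their observed length, so a
cell stuck in one state for the whole window contributes a single run of
the full measurement time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .model import Trajectory

__all__ = [
    "SAVGOL_FRAME_MIN",
    "DynamicityResult",
    "smooth",
    "segment_states",
    "dynamicity",
    "half_cycle_dc",
    "mean_persistence",
    "population_threshold",
    "analyze_cells",
]

SAVGOL_FRAME_MIN = 165.0  # smoothing frame length, minutes


@dataclass
class DynamicityResult:
    """High/low statistics of one cell trace."""

    threshold: float
    high_times: np.ndarray = field(repr=False)
    low_times: np.ndarray = field(repr=False)
    t_measure: float = 0.0

    @property
    def alpha_up(self) -> float:
        return float(np.sum(self.high_times) / self.t_measure)

    @property
    def alpha_down(self) -> float:
        return float(np.sum(self.low_times) / self.t_measure)

    @property
    def dc(self) -> float:
        return 2.0 * min(self.alpha_up, self.alpha_down)

    @property
    def mean_high(self) -> float:
        return float(np.mean(self.high_times)) if self.high_times.size else float("nan")

    @property
    def mean_low(self) -> float:
        return float(np.mean(self.low_times)) if self.low_times.size else float("nan")


def smooth(trace, dt_min: float = 1.0) -> np.ndarray:
    """Order-1 Savitzky-Golay smoothing with a 165-minute frame.

    The frame is ``round(165 / dt)`` samples, forced odd.  Reproduces
    constants and linear ramps exactly (an order-1 local fit).
    """
    x = np.asarray(trace, dtype=float)
    frame = int(round(SAVGOL_FRAME_MIN / dt_min))
    if frame % 2 == 0:
        frame += 1
    if x.shape[-1] < frame:
        raise ValueError(f"trace shorter than the {frame}-sample smoothing frame")
    return savgol_filter(x, frame, polyorder=1, axis=-1)


def segment_states(trace, threshold: float, dt_h: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Run durations (hours) above and at-or-below a threshold.

    Maximal runs strictly above the threshold are high states; samples
    exactly at the threshold count as low.  First and last (censored)
    runs are included.  Each sample contributes ``dt_h`` hours, so the
    durations partition the measurement time exactly.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("trace must be a non-empty 1-D array")
    high = x > threshold
    # run-length encode
    change = np.flatnonzero(high[1:] != high[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [x.size]))
    lengths = (ends - starts) * dt_h
    states = high[starts]
    return lengths[states], lengths[~states]


def dynamicity(high_times, low_times, t_measure: float) -> float:
    """Dynamicity coefficient ``2 * min(alpha_up, alpha_down)`` in [0, 1]."""
    if t_measure <= 0:
        raise ValueError("t_measure must be positive")
    a_up = float(np.sum(high_times)) / t_measure
    a_down = float(np.sum(low_times)) / t_measure
    return 2.0 * min(a_up, a_down)


def half_cycle_dc(n_c: float) -> float:
    """Dynamicity of a perfect switcher observed for a half-integer
    number of cycles: ``2 (n_c - 1/2) / (2 (n_c - 1/2) + 1)``."""
    if n_c < 0.5 or abs((n_c - 0.5) % 1.0) > 1e-9:
        raise ValueError("n_c must be one of 0.5, 1.5, 2.5, ...")
    k = 2.0 * (n_c - 0.5)
    return k / (k + 1.0)


def mean_persistence(high_times, low_times) -> tuple[float, float]:
    """Mean high- and low-state persistence times (hours).

    For a regular switcher their sum is the switching period.  An empty
    run list yields NaN for that state.
    """
    h = np.asarray(high_times, dtype=float)
    low = np.asarray(low_times, dtype=float)
    mh = float(h.mean()) if h.size else float("nan")
    ml = float(low.mean()) if low.size else float("nan")
    return mh, ml


def population_threshold(traj: Trajectory, last_h: float | None = 150.0) -> float:
    """Mean protein over all cells and recorded times of the window."""
    if last_h is not None:
        traj = traj.window(last_h)
    return float(traj.p.mean())


def analyze_cells(traj: Trajectory, last_h: float | None = 150.0,
                  threshold: float | None = None
                  ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Smooth, segment and score every cell of a trajectory.

    Returns a per-cell table (``cell, alpha_up, alpha_down, dc,
    mean_high_h, mean_low_h``) and the pooled run durations
    ``{"high": ..., "low": ...}`` (hours) for histogramming across
    replicates.  One relative threshold -- the population mean over the
    window -- is used for the whole simulation unless given explicitly.
    """
    if last_h is not None:
        traj = traj.window(last_h)
    p = traj.protein_flat()  # (K, n_cells)
    dt_min = float(traj.times_min[1] - traj.times_min[0])
    dt_h = dt_min / 60.0
    t_measure = p.shape[0] * dt_h
    if threshold is None:
        threshold = float(p.mean())
    smoothed = smooth(p.T, dt_min=dt_min)  # (n_cells, K)

    rows = []
    pooled_high: list[np.ndarray] = []
    pooled_low: list[np.ndarray] = []
    for cell in range(smoothed.shape[0]):
        high, low = segment_states(smoothed[cell], threshold, dt_h)
        res = DynamicityResult(threshold=threshold, high_times=high,
                               low_times=low, t_measure=t_measure)
        rows.append(
            {
                "cell": cell,
                "alpha_up": res.alpha_up,
                "alpha_down": res.alpha_down,
                "dc": res.dc,
                "mean_high_h": res.mean_high,
                "mean_low_h": res.mean_low,
            }
        )
        pooled_high.append(high)
        pooled_low.append(low)
    table = pd.DataFrame(rows)
    runs = {
        "high": np.concatenate(pooled_high) if pooled_high else np.array([]),
        "low": np.concatenate(pooled_low) if pooled_low else np.array([]),
    }
    return table, runs
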