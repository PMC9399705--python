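"""Differentiation events and the differentiation-based perturbation (DBP).

Cells with low HES5 are more likely to commit to differentiation.  At each
step every cell below the differentiation threshold (the instantaneous
population mean protein) fires independently with hazard

    lambda(p) = R * (D_thresh - p) / D_thresh     [events / h],

zero above threshold.  A differentiating cell transiently raises Notch
signalling in a small group of contacting progenitors (increased Delta and
Mib1 presentation during delamination); the model abstracts this as a
fold-increase ``F_pert`` of the HES5 transcription rate in the group for a
fixed window ``T_pert``.  Cell movement is not modelled: the
differentiating cell itself stays on the lattice and only its signalling
footprint is represented.

The absolute event-rate constant ``R`` is not constrained by the kinetic
parameters; it sets the overall scale of differentiation.  The packaged
default ``DEFAULT_R`` was calibrated once against the stationary-pattern
reference condition (strong lateral inhibition, no perturbation) so that
the population differentiation rate sits at the experimentally motivated
scale of a few percent of the population per hour; all conditions share
the same value, so rate *contrasts* between patterning regimes are
independent of the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import LatticeSpec

__all__ = [
    "DEFAULT_R",
    "DBPConfig",
    "DiffEvent",
    "differentiation_hazard",
    "select_events",
    "build_perturbation_group",
    "differentiation_rate",
    "per_cell_frequency",
]

# Calibrated once (see module docstring); events per hour at zero expression.
DEFAULT_R = 0.2026


@dataclass(frozen=True)
class DBPConfig:
    """Settings of the differentiation selection and perturbation.

    ``R`` is the differentiation rate constant (per hour, reached at zero
    expression); ``F_pert`` the transcription-rate fold change applied to
    the perturbed group; ``T_pert`` the perturbation duration in hours.
    With ``perturbation_enabled`` false, events are still selected and
    logged but leave the dynamics untouched (the stationary-pattern
    control).  ``refractory`` optionally blocks new events inside an
    active perturbation group until it expires; the default keeps every
    below-threshold cell eligible at every step, the plain reading of
    the selection hazard.
    """

    R: float = DEFAULT_R
    F_pert: float = 3.0
    T_pert: float = 7.0
    perturbation_enabled: bool = True
    refractory: bool = False

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("R must be non-negative")
        if self.F_pert <= 0:
            raise ValueError("F_pert must be positive")
        if self.T_pert < 0:
            raise ValueError("T_pert must be non-negative")


@dataclass(frozen=True)
class DiffEvent:
    """One differentiation event: the firing cell and its perturbed group."""

    time_h: float
    row: int
    col: int
    group: tuple[tuple[int, int], ...]
    perturbation_applied: bool


def differentiation_hazard(p, d_thresh: float, R: float):
    """Per-hour differentiation hazard of cells at protein level ``p``.

    Linear in the shortfall below ``d_thresh`` and zero at or above it.
    """
    if d_thresh <= 0:
        raise ValueError("d_thresh must be positive")
    p = np.asarray(p, dtype=float)
    return np.where(p < d_thresh, R * (d_thresh - p) / d_thresh, 0.0)


def select_events(protein_state, d_thresh: float, R: float, dt_min: float,
                  rng: np.random.Generator,
                  eligible=None) -> np.ndarray:
    """Indices of cells firing a differentiation event this step.

    Each eligible cell fires independently with probability
    ``hazard * dt`` (dt in hours) -- the first-order discretisation of the
    hazard.  ``eligible`` masks out cells inside active perturbation
    groups (refractory rule).
    """
    p = np.asarray(protein_state, dtype=float)
    dt_h = dt_min / 60.0
    if R * dt_h > 1.0:
        import warnings

        warnings.warn("R * dt exceeds 1: firing probability saturates")
    prob = differentiation_hazard(p, d_thresh, R) * dt_h
    u = rng.random(p.size)
    fired = u < prob
    if eligible is not None:
        fired &= np.asarray(eligible, dtype=bool)
    return np.flatnonzero(fired)


def build_perturbation_group(cell: tuple[int, int], spec: LatticeSpec,
                             rng: np.random.Generator) -> list[tuple[int, int]]:
    """Cells receiving the perturbation around a differentiating cell.

    Single column: the cell plus, with equal probability, the cell above
    or below (at a boundary, the existing option).  Two dimensions: the
    cell and its column partner ``(i, j+1)`` (``j-1`` when ``j+1`` is off
    the lattice), plus -- with equal probability -- the matching pair one
    row above or below; members falling outside the lattice are dropped.
    """
    i, j = cell
    rows, cols = spec.n_rows, spec.n_cols
    if not (0 <= i < rows and 0 <= j < cols):
        raise ValueError("cell outside lattice")

    if cols == 1:
        if rows == 1:
            return [(i, j)]
        if i == 0:
            partner = 1
        elif i == rows - 1:
            partner = rows - 2
        else:
            partner = i - 1 if rng.random() < 0.5 else i + 1
        return [(i, 0), (partner, 0)]

    jp = j + 1 if j + 1 < cols else j - 1
    ip = i - 1 if rng.random() < 0.5 else i + 1
    group = [(i, j), (i, jp), (ip, j), (ip, jp)]
    return [(r, c) for r, c in group if 0 <= r < rows and 0 <= c < cols]


def differentiation_rate(events, n_cells: int, duration_h: float) -> float:
    """Population differentiation rate: events/h as a percent of cell count."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    return 100.0 * (len(events) / duration_h) / n_cells


def per_cell_frequency(events, n_cells: int, duration_h: float,
                       n_cols: int = 1) -> np.ndarray:
    """Events per hour for every cell (input for frequency histograms)."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    counts = np.zeros(n_cells)
    for e in events:
        counts[e.row * n_cols + e.col] += 1
    return counts / duration_h


def events_dataframe(events) -> pd.DataFrame:
    rows = [
        {
            "time_h": e.time_h,
            "cell_row": e.row,
            "cell_col": e.col,
            "group_members": ";".join(f"{r},{c}" for r, c in e.group),
            "perturbation_applied": e.perturbation_applied,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows, columns=["time_h", "cell_row", "cell_col", "group_members",
                       "perturbation_applied"])
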