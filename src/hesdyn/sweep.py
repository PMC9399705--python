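"""Parameter-space sweeps over coupling strength and signalling reach.

Replicated simulations are run on a grid of (lateral-inhibition
repression threshold ``P0_LI``) x (distal signalling efficiency
``eps_d/eps_p``).  Each grid point is summarised by three metrics over
the post-burn-in window, averaged across replicates:

* mean significant spatial period (cells),
* occurrence of significant spatial periodicity,
* mean dynamicity coefficient (cell average).

A grid point supports *dynamic spatial patterning* when

    period > 3  and  occurrence > 0.4  and  dynamicity > 0.4

(all strict) -- the regime matching the three-to-four-cell periodic,
temporally switching expression seen in the neural tube.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differentiation import DBPConfig
from .lattice import LatticeSpec
from .model import ModelParams, SimConfig, simulate
from .spatial import analyze_spatial, mean_significant_period, occurrence
from .temporal import analyze_cells

__all__ = ["SweepSpec", "ParamSpaceCell", "run_sweep", "classify_dynamic",
           "replicate_metrics"]

logger = logging.getLogger(__name__)

PERIOD_MIN = 3.0
OCCURRENCE_MIN = 0.4
DC_MIN = 0.4


@dataclass(frozen=True)
class ParamSpaceCell:
    """Replicate-averaged metrics at one (P0_LI, eps_ratio) grid point."""

    p0_li: float
    eps_ratio: float
    period: float       # NaN when no replicate had a significant period
    occ: float
    dc: float

    @property
    def passes_region(self) -> bool:
        return classify_dynamic(self)


def classify_dynamic(cell: ParamSpaceCell) -> bool:
    """Strict three-way criterion for dynamic spatial patterning."""
    if not np.isfinite(cell.period):
        return False
    return (cell.period > PERIOD_MIN and cell.occ > OCCURRENCE_MIN
            and cell.dc > DC_MIN)


@dataclass(frozen=True)
class SweepSpec:
    """Grid, replication and per-run configuration of a sweep."""

    p0_li_grid: tuple[float, ...]
    eps_grid: tuple[float, ...]
    replicates: int = 20
    lattice: LatticeSpec = field(default_factory=lambda: LatticeSpec(26, 1))
    params: ModelParams = field(default_factory=ModelParams)
    sim: SimConfig = field(default_factory=lambda: SimConfig(duration_h=300.0))
    dbp: DBPConfig | None = None
    analysis_window_h: float = 150.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.p0_li_grid or not self.eps_grid:
            raise ValueError("grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def replicate_seed(master_seed: int, i: int, j: int, rep: int) -> int:
    """Deterministic per-replicate seed from the master seed and indices."""
    ss = np.random.SeedSequence([master_seed, i, j, rep])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def replicate_metrics(params: ModelParams, lattice: LatticeSpec,
                      sim: SimConfig, dbp: DBPConfig | None,
                      eps_ratio: float, window_h: float
                      ) -> tuple[float, float, float]:
    """(significant period, occurrence, mean Dc) of one simulation."""
    traj = simulate(params, lattice, sim, dbp=dbp, eps_ratio=eps_ratio)
    table = analyze_spatial(traj, last_h=window_h)
    occ = occurrence(table["p_val"].to_numpy())
    period = mean_significant_period(table)
    cells, _ = analyze_cells(traj, last_h=window_h)
    return period, occ, float(cells["dc"].mean())


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Replicated sweep over the parameter grid.

    Returns a tidy frame with one row per grid point: ``p0_li,
    eps_ratio, period, occ, dc, passes``.  The period is averaged over
    replicates that detected a significant period (NaN if none did);
    occurrence and dynamicity over all successful replicates.  Failed
    replicates are logged and excluded, never silently dropped.
    """
    rows = []
    for i, p0 in enumerate(spec.p0_li_grid):
        for j, eps in enumerate(spec.eps_grid):
            params = ModelParams(
                **{**spec.params.__dict__, "p0_li": float(p0),
                   "coupling_enabled": p0 > 0}
            )
            periods, occs, dcs = [], [], []
            for rep in range(spec.replicates):
                seed = replicate_seed(spec.master_seed, i, j, rep)
                sim = SimConfig(**{**spec.sim.__dict__, "seed": seed})
                try:
                    period, occ, dc = replicate_metrics(
                        params, spec.lattice, sim, spec.dbp, float(eps),
                        spec.analysis_window_h,
                    )
                except FloatingPointError as err:
                    logger.warning(
                        "replicate (p0_li=%s, eps=%s, rep=%d) failed: %s",
                        p0, eps, rep, err,
                    )
                    continue
                periods.append(period)
                occs.append(occ)
                dcs.append(dc)
                logger.info(
                    "p0_li=%s eps=%s rep=%d: period=%.2f occ=%.2f dc=%.2f",
                    p0, eps, rep,
                    period if np.isfinite(period) else float("nan"), occ, dc,
                )
            period_arr = np.asarray(periods)
            mean_period = (float(np.nanmean(period_arr))
                           if np.isfinite(period_arr).any() else float("nan"))
            cell = ParamSpaceCell(
                p0_li=float(p0), eps_ratio=float(eps),
                period=mean_period,
                occ=float(np.mean(occs)) if occs else float("nan"),
                dc=float(np.mean(dcs)) if dcs else float("nan"),
            )
            rows.append(
                {
                    "p0_li": cell.p0_li, "eps_ratio": cell.eps_ratio,
                    "period": cell.period, "occ": cell.occ, "dc": cell.dc,
                    "passes": cell.passes_region,
                }
            )
    return pd.DataFrame(rows)
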