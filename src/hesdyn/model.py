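"""Coupled stochastic delay differential equations for HES5 expression.

Each cell carries HES5 mRNA ``m`` and protein ``p``.  mRNA production is
repressed by the cell's own (delayed) protein through a decreasing Hill
function, and by the averaged (weighted) protein of its signalling
neighbours through a second Hill function -- the lateral-inhibition
coupling.  Intrinsic noise follows the chemical Langevin form: each
reaction channel contributes Gaussian noise with variance equal to its
propensity, so

    dm = (-mu_m m + A) dt + sqrt(mu_m m + A) dW_m,   A = alpha_m H_auto H_LI
    dp = (-mu_p p + alpha_p m) dt + sqrt(mu_p p + alpha_p m) dW_p

integrated with the Euler-Maruyama scheme and a constant-history delay
buffer.  Deterministic mode drops the noise terms.  A differentiation
process (see :mod:`hesdyn.differentiation`) can transiently scale the
transcription rate of cells contacting a differentiating neighbour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lattice import LatticeSpec, NeighbourMap, build_lattice, weight_matrix

__all__ = [
    "ModelParams",
    "SimConfig",
    "Trajectory",
    "hill_auto",
    "hill_li",
    "mean_neighbour_protein",
    "fixed_point",
    "simulate",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the coupled HES5 model.

    Defaults are the neural-tube single-cell rates inferred from live
    imaging, with the lateral-inhibition threshold ``p0_li`` at a mid-range
    value used by most of the multicellular runs.

    Units: rates in 1/min, delays in min, thresholds in protein molecules.
    """

    alpha_m: float = 0.77          # transcription rate
    alpha_p: float = 26.0          # translation rate
    mu_m: float = LN2 / 30.0       # mRNA half-life 30 min
    mu_p: float = LN2 / 90.0       # protein half-life 90 min
    p0_auto: float = 25_000.0      # auto-repression threshold
    p0_li: float = 4_000.0         # lateral-inhibition repression threshold
    n_auto: float = 3.5
    n_li: float = 3.0
    tau_auto: float = 30.0         # auto-repression delay
    tau_li: float = 0.0            # lateral-inhibition delay
    coupling_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_m", "alpha_p", "mu_m", "mu_p", "p0_auto",
                     "n_auto", "n_li"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_auto < 0 or self.tau_li < 0:
            raise ValueError("delays must be non-negative")
        if self.coupling_enabled and self.p0_li <= 0:
            raise ValueError("p0_li must be positive when coupling is enabled")

    def uncoupled(self) -> "ModelParams":
        return replace(self, coupling_enabled=False)


def hill_auto(p_delayed, params: ModelParams):
    """Auto-repression factor ``1 / (1 + (p/P0_auto)^n_auto)`` in (0, 1]."""
    x = np.asarray(p_delayed, dtype=float) / params.p0_auto
    return 1.0 / (1.0 + x**params.n_auto)


def hill_li(pbar_delayed, params: ModelParams):
    """Lateral-inhibition factor in response to averaged neighbour protein.

    Identically 1 when coupling is disabled (the uncoupled model).
    """
    if not params.coupling_enabled:
        return np.ones_like(np.asarray(pbar_delayed, dtype=float))
    x = np.asarray(pbar_delayed, dtype=float) / params.p0_li
    return 1.0 / (1.0 + x**params.n_li)


def mean_neighbour_protein(p_flat, nmap: NeighbourMap, cell: int,
                           eps_ratio: float, norm: str = "capacity") -> float:
    """Weighted mean protein over a cell's signalling neighbours.

    Proximal neighbours weigh 1, distal neighbours ``eps_ratio``; the sum
    is divided by the geometry's full contact count (``norm="capacity"``,
    the default used by the integrator) or by the cell's realised
    neighbour count (``norm="count"``, the plain weighted average).  A
    cell with no neighbours returns 0 (and the LI factor is bypassed in
    the integrator).
    """
    p_flat = np.asarray(p_flat, dtype=float)
    prox, dist = nmap.proximal[cell], nmap.distal[cell]
    if len(prox) + len(dist) == 0:
        return 0.0
    if norm == "capacity":
        total = 6 + (4 if nmap.spec.include_distal else 0)
    elif norm == "count":
        total = len(prox) + len(dist)
    else:
        raise ValueError(f"unknown normalisation {norm!r}")
    return float((p_flat[prox].sum() + eps_ratio * p_flat[dist].sum()) / total)


def fixed_point(params: ModelParams) -> tuple[float, float]:
    """Steady state (m*, p*) of the uncoupled deterministic single cell.

    Solves ``mu_m mu_p p / (alpha_m alpha_p) = H_auto(p)`` by bracketing
    root finding; the steady state is unique because the left side is
    increasing and the right side strictly decreasing.
    """
    scale = params.mu_m * params.mu_p / (params.alpha_m * params.alpha_p)

    def f(p):
        return scale * p - 1.0 / (1.0 + (p / params.p0_auto) ** params.n_auto)

    hi = 1.0 / scale  # f(hi) = 1 - H_auto(hi) > 0
    p_star = brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-14)
    m_star = params.mu_p * p_star / params.alpha_p
    return m_star, p_star


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    ``dt`` (min) is the Euler-Maruyama step; ``record_interval`` (min) must
    be an integer multiple of it.  Initial protein is drawn per cell
    uniformly in ``[init_low, init_high] * p0_auto`` with mRNA at the
    corresponding translation balance ``m = mu_p p / alpha_p``.
    """

    dt: float = 1.0
    duration_h: float = 300.0
    record_interval: float = 1.0
    seed: int = 0
    stochastic: bool = True
    init_low: float = 0.5
    init_high: float = 1.5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ratio = self.record_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("record_interval must be an integer multiple of dt")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")


@dataclass
class Trajectory:
    """Recorded simulation output.

    ``m`` and ``p`` have shape ``(n_times, n_rows, n_cols)`` (molecules);
    ``times_min`` is the uniform recording grid.  ``events`` logs
    differentiation events (see :class:`hesdyn.differentiation.DiffEvent`).
    """

    spec: LatticeSpec
    times_min: np.ndarray = field(repr=False)
    m: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    events: list = field(default_factory=list, repr=False)

    @property
    def times_h(self) -> np.ndarray:
        return self.times_min / 60.0

    @property
    def n_cells(self) -> int:
        return self.spec.n_cells

    @property
    def duration_h(self) -> float:
        return float(self.times_min[-1] / 60.0)

    def protein_flat(self) -> np.ndarray:
        """Protein as a (n_times, n_cells) array (row-major cell order)."""
        return self.p.reshape(self.p.shape[0], -1)

    def window(self, last_h: float) -> "Trajectory":
        """Restrict to the final ``last_h`` hours (burn-in removal)."""
        t0 = self.times_min[-1] - last_h * 60.0
        keep = self.times_min >= t0 - 1e-9
        return Trajectory(
            spec=self.spec,
            times_min=self.times_min[keep],
            m=self.m[keep],
            p=self.p[keep],
            events=[e for e in self.events if e.time_h * 60.0 >= t0 - 1e-9],
        )

    def event_dataframe(self) -> pd.DataFrame:
        from .differentiation import events_dataframe

        return events_dataframe(self.events)

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, times_min=self.times_min, m=self.m, p=self.p,
            n_rows=self.spec.n_rows, n_cols=self.spec.n_cols,
        )


def _initial_state(params: ModelParams, n_cells: int, config: SimConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    p0 = rng.uniform(config.init_low, config.init_high, size=n_cells) * params.p0_auto
    m0 = params.mu_p * p0 / params.alpha_p
    return m0, p0


def simulate(params: ModelParams,
             lattice: LatticeSpec | NeighbourMap,
             config: SimConfig,
             dbp=None,
             eps_ratio: float = 1.5,
             coupling_norm: str = "capacity") -> Trajectory:
    """Integrate the lattice model and return the recorded trajectory.

    Parameters
    ----------
    params, config
        Kinetics and integration settings.
    lattice
        Lattice geometry (a spec, or a prebuilt neighbour map).
    dbp
        Optional :class:`hesdyn.differentiation.DBPConfig`; when given, the
        probabilistic differentiation selection runs every step and (if
        enabled) applies the transcription-rate perturbation to the chosen
        cell groups.
    eps_ratio
        Distal/proximal signalling efficiency ``eps_d / eps_p``.
    coupling_norm
        Denominator convention of the neighbour average; see
        :func:`hesdyn.lattice.weight_matrix`.

    The same seed and configuration yield a bit-identical trajectory.  Four
    independent RNG streams (initial condition, Langevin noise,
    differentiation selection, group choice) are spawned from the seed, so
    e.g. disabling the perturbation does not re-shuffle the noise.
    """
    from . import differentiation as diff

    nmap = lattice if isinstance(lattice, NeighbourMap) else build_lattice(lattice)
    spec = nmap.spec
    n = spec.n_cells

    dt = config.dt
    n_steps = round(config.duration_h * 60.0 / dt)
    rec_every = round(config.record_interval / dt)
    d_auto = round(params.tau_auto / dt)
    d_li = round(params.tau_li / dt)
    max_delay_min = max(params.tau_auto, params.tau_li)
    if config.duration_h * 60.0 <= max_delay_min:
        raise ValueError("duration must exceed the longest delay")
    buf_len = max(d_auto, d_li) + 1

    ss = np.random.SeedSequence(config.seed)
    init_rng, noise_rng, sel_rng, grp_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    m, p = _initial_state(params, n, config, init_rng)
    hist = np.tile(p, (buf_len, 1))  # constant pre-history

    coupled = params.coupling_enabled and any(
        len(nmap.proximal[i]) + len(nmap.distal[i]) > 0 for i in range(n)
    )
    W = weight_matrix(nmap, eps_ratio, norm=coupling_norm) if coupled else None

    dbp_active = dbp is not None and dbp.R > 0
    if dbp_active:
        max_prob = dbp.R * dt / 60.0
        if max_prob > 1.0:
            import warnings

            warnings.warn("R * dt exceeds 1: per-step firing probability saturates")
    pert_until = np.full(n, -np.inf)  # minutes
    events: list = []

    n_rec = n_steps // rec_every + 1
    times = np.empty(n_rec)
    rec_m = np.empty((n_rec, n))
    rec_p = np.empty((n_rec, n))
    k = 0

    sqrt_dt = math.sqrt(dt)
    dt_h = dt / 60.0

    for step in range(n_steps):
        t = step * dt
        hist[step % buf_len] = p

        if step % rec_every == 0:
            if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
                raise FloatingPointError(
                    f"non-finite state at t = {t / 60.0:.2f} h "
                    "(try a smaller dt)"
                )
            times[k] = t
            rec_m[k] = m
            rec_p[k] = p
            k += 1

        p_auto = hist[(step - d_auto) % buf_len]
        h = hill_auto(p_auto, params)
        if coupled:
            pbar = W @ hist[(step - d_li) % buf_len]
            h = h * hill_li(pbar, params)

        prod_m = params.alpha_m * h
        if dbp_active:
            perturbed = t < pert_until
            if perturbed.any():
                prod_m = np.where(perturbed, dbp.F_pert * prod_m, prod_m)
        prod_p = params.alpha_p * m
        drift_m = prod_m - params.mu_m * m
        drift_p = prod_p - params.mu_p * p

        if config.stochastic:
            xi = noise_rng.standard_normal((2, n))
            m = m + dt * drift_m + sqrt_dt * np.sqrt(params.mu_m * m + prod_m) * xi[0]
            p = p + dt * drift_p + sqrt_dt * np.sqrt(params.mu_p * p + prod_p) * xi[1]
            np.maximum(m, 0.0, out=m)
            np.maximum(p, 0.0, out=p)
        else:
            m = m + dt * drift_m
            p = p + dt * drift_p

        if dbp_active:
            t1 = t + dt
            u = sel_rng.random(n)  # drawn every step: frozen stream layout
            d_thresh = float(p.mean())
            if d_thresh > 0:
                hazard = diff.differentiation_hazard(p, d_thresh, dbp.R)
                eligible = np.ones(n, dtype=bool)
                if dbp.perturbation_enabled and dbp.refractory:
                    eligible = ~(t1 < pert_until)
                fired = eligible & (u < hazard * dt_h)
                for cell in np.flatnonzero(fired):
                    row, col = divmod(int(cell), spec.n_cols)
                    group = diff.build_perturbation_group(
                        (row, col), spec, grp_rng
                    )
                    if dbp.perturbation_enabled:
                        flat = [spec.flat_index(r, c) for r, c in group]
                        pert_until[flat] = np.maximum(
                            pert_until[flat], t1 + dbp.T_pert * 60.0
                        )
                    events.append(
                        diff.DiffEvent(
                            time_h=t1 / 60.0,
                            row=row,
                            col=col,
                            group=tuple(group),
                            perturbation_applied=bool(dbp.perturbation_enabled),
                        )
                    )

    times[k] = n_steps * dt
    rec_m[k] = m
    rec_p[k] = p

    shape = (n_rec, spec.n_rows, spec.n_cols)
    return Trajectory(
        spec=spec,
        times_min=times,
        m=rec_m.reshape(shape),
        p=rec_p.reshape(shape),
        events=events,
    )
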