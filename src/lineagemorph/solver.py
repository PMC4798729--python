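"""Orchestration of full spatial simulations.

Per step (the quasi-steady ordering — factor diffusion equilibrates in
minutes, growth acts over cell cycles):

1. re-impose the stem-cell band on the basement membrane;
2. solve the quasi-steady fields ``[F]`` and ``[G]``;
3. evaluate the self-renewal field ``p1``;
4. evaluate the lineage sources;
5. solve the Darcy pressure equation and evaluate the velocity;
6. advance the volume fractions (advection + Fickian flux + sources).

Steps are retried with a halved ``dt`` when the fraction bounds are
violated (bounded number of retries).  A simulation terminates at
``t_end``, on epithelial extinction (total area below 1% of its initial
value), or when the tissue reaches the top of the computational box.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fields import (
    ExoSourceSpec,
    FieldState,
    Grid2D,
    SpatialParams,
    advance_fractions,
    chemical_potential,
    exogenous_source,
    lineage_sources,
    self_renewal_field,
    solve_quasi_steady_factor,
    stem_cell_layer,
    velocity_and_pressure,
)

__all__ = ["SimulationConfig", "SimulationResult", "step", "run_simulation"]


@dataclass
class SimulationConfig:
    """Everything needed to run one spatial scenario."""

    grid: Grid2D = field(default_factory=Grid2D)
    params: SpatialParams = field(default_factory=SpatialParams)
    exo_sources: tuple[ExoSourceSpec, ...] = ()
    t_end: float = 24.0
    dt: float = 0.005
    snapshot_every: float = 1.0
    seed: int = 0
    noise_p1_var: float = 0.0     # optional spatiotemporal noise on p1
    noise_sc_var: float = 0.0     # optional noise on the SC output
    max_dt_halvings: int = 6

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class SimulationResult:
    """Snapshots and time series of one run."""

    snapshots: list[FieldState]
    times: np.ndarray
    area_total: np.ndarray
    area_cp: np.ndarray
    area_td: np.ndarray
    max_feedback_ratio: np.ndarray   # max phi[F] / (gamma[G] + 1e-3)
    termination: str = "t_end"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.times,
            "area_total": self.area_total,
            "area_cp": self.area_cp,
            "area_td": self.area_td,
            "max_feedback_ratio": self.max_feedback_ratio,
        })


def _leftmost_bm_height(chiS: np.ndarray, grid: Grid2D) -> float:
    """y_C: BM height (0.5 crossing of the stroma fraction) in the leftmost
    column, used to anchor the exogenous Gaussian sources."""
    col = chiS[:, 0]
    y = grid.y
    above = col < 0.5
    if not above.any() or above.all():
        return grid.y0
    i = int(np.argmax(above))
    if i == 0:
        return grid.y0
    f = (col[i - 1] - 0.5) / max(col[i - 1] - col[i], 1e-12)
    return float(y[i - 1] + f * (y[i] - y[i - 1]))


def _noise_field(rng, var, shape):
    if var <= 0:
        return None
    return rng.normal(0.0, math.sqrt(var), size=shape)


def step(state: FieldState, dt: float, config: SimulationConfig,
         rng: np.random.Generator | None = None,
         p1_noise: np.ndarray | None = None,
         sc_noise: np.ndarray | None = None) -> FieldState:
    """Advance the full model by one time step of size ``dt``."""
    params = config.params
    grid = config.grid

    chi_bulk = state.chi1 + state.chi2
    chi0 = stem_cell_layer(chi_bulk, state.chiS, grid, params)
    if sc_noise is not None:
        chi0 = np.clip(chi0 * (1.0 + sc_noise), 0.0, None)
    state.chi0 = chi0
    chiL = state.chiL
    y_C = _leftmost_bm_height(state.chiS, grid)

    exo_F = next((s for s in config.exo_sources if s.factor == "F"), None)
    exo_G = next((s for s in config.exo_sources if s.factor == "G"), None)
    remF, srcF = exogenous_source(exo_F, state.chiS, grid, y_C, state.time,
                                  u_stroma=params.factor_F.u_stroma)
    remG, srcG = exogenous_source(exo_G, state.chiS, grid, y_C, state.time,
                                  u_stroma=params.factor_G.u_stroma)
    F = solve_quasi_steady_factor(grid, state.chi1, state.chi2, chiL,
                                  params.factor_F, remF, srcF)
    G = solve_quasi_steady_factor(grid, state.chi1, state.chi2, chiL,
                                  params.factor_G, remG, srcG)

    p1 = self_renewal_field(F, G, params)
    if p1_noise is not None:
        p1 = np.clip(p1 + p1_noise, 0.0, 1.0)
    src1, src2, srcT = lineage_sources(chi0, state.chi1, state.chi2, p1, params)

    bulk = state.chi_bulk
    mu = chemical_potential(bulk, grid, params)
    pressure, (ufx, ufy) = velocity_and_pressure(srcT, mu, bulk, grid,
                                                 params, chiS=state.chiS)

    new = advance_fractions(state, dt, params, src1, src2, mu, ufx, ufy)
    new.F, new.G, new.pressure, new.mu = F, G, pressure, mu
    new.ux = _faces_to_centers_x(ufx, grid)
    new.uy = _faces_to_centers_y(ufy, grid)
    return new


def _faces_to_centers_x(ufx: np.ndarray, grid: Grid2D) -> np.ndarray:
    if grid.periodic_x:
        f = ufx.reshape(grid.ny, grid.nx)
        return 0.5 * (f + np.roll(f, -1, axis=1))
    f = ufx.reshape(grid.ny, grid.nx + 1)
    return 0.5 * (f[:, :-1] + f[:, 1:])


def _faces_to_centers_y(ufy: np.ndarray, grid: Grid2D) -> np.ndarray:
    f = ufy.reshape(grid.ny + 1, grid.nx)
    return 0.5 * (f[:-1, :] + f[1:, :])


def _cfl_dt(ufx: np.ndarray, ufy: np.ndarray, grid: Grid2D,
            cfl: float = 0.4) -> float:
    vmax = max(float(np.max(np.abs(ufx))), float(np.max(np.abs(ufy))), 1e-12)
    return cfl * min(grid.dx, grid.dy) / vmax


def run_simulation(config: SimulationConfig,
                   initial_state: FieldState,
                   progress: Callable[[float], None] | None = None,
                   wall_time_limit: float | None = None) -> SimulationResult:
    """Run a spatial simulation to ``t_end`` or a terminal condition.

    Deterministic for a given config (including seed).  Snapshots are
    recorded at the requested cadence (and at the final time); the time
    series of areas and the feedback-ratio diagnostic are recorded at
    every snapshot.
    """
    params = config.params
    grid = config.grid
    rng = np.random.default_rng(config.seed)
    state = initial_state.copy()

    snapshots: list[FieldState] = []
    times: list[float] = []
    a_tot: list[float] = []
    a_cp: list[float] = []
    a_td: list[float] = []
    ratio: list[float] = []
    termination = "t_end"

    area0 = grid.integrate(state.chi1 + state.chi2)
    next_snap = 0.0
    t = state.time
    start = _time.monotonic()

    def record(s: FieldState) -> None:
        if s.F is None or s.G is None:
            # initial snapshot: factors not yet computed by a step
            s.F = solve_quasi_steady_factor(grid, s.chi1, s.chi2, s.chiL,
                                            params.factor_F)
            s.G = solve_quasi_steady_factor(grid, s.chi1, s.chi2, s.chiL,
                                            params.factor_G)
        snapshots.append(s.copy())
        times.append(s.time)
        a_cp.append(grid.integrate(s.chi1))
        a_td.append(grid.integrate(s.chi2))
        a_tot.append(grid.integrate(s.chiT))
        r = params.phi * s.F / (params.gamma * s.G + 1e-3)
        ratio.append(float(np.max(r)))

    # resample spatiotemporal noise once per cell cycle
    noise_cycle = -1
    p1_noise = sc_noise = None

    while t < config.t_end - 1e-9:
        if wall_time_limit is not None and \
                _time.monotonic() - start > wall_time_limit:
            termination = "wall_time"
            break
        cyc = int(t)
        if cyc != noise_cycle:
            noise_cycle = cyc
            p1_noise = _noise_field(rng, config.noise_p1_var, grid.shape)
            sc_noise = _noise_field(rng, config.noise_sc_var, grid.shape)

        if t >= next_snap - 1e-9:
            try:
                bulk = state.chi1 + state.chi2
                state.chi0 = stem_cell_layer(bulk, state.chiS, grid, params)
            except RuntimeError:
                pass
            record(state)
            next_snap += config.snapshot_every
            if progress is not None:
                progress(t)

        dt = min(config.dt, config.t_end - t, next_snap - t + 1e-12)
        done = False
        for attempt in range(config.max_dt_halvings + 1):
            try:
                new = step(state, dt, config, rng=rng,
                           p1_noise=p1_noise, sc_noise=sc_noise)
                done = True
                break
            except FloatingPointError:
                dt *= 0.5
            except RuntimeError as exc:
                termination = f"terminal: {exc}"
                done = False
                break
        if not done:
            if not termination.startswith("terminal"):
                termination = "step_failure"
            break
        state = new
        t = state.time

        area = grid.integrate(state.chi1 + state.chi2)
        if area < 0.01 * area0:
            termination = "extinction"
            break
        # domain breach: tissue reaching the top rows of the box
        if np.any(state.chi1[-2, :] + state.chi2[-2, :] > 0.5):
            termination = "domain_breach"
            break

    record(state)
    return SimulationResult(
        snapshots=snapshots,
        times=np.asarray(times),
        area_total=np.asarray(a_tot),
        area_cp=np.asarray(a_cp),
        area_td=np.asarray(a_td),
        max_feedback_ratio=np.asarray(ratio),
        termination=termination)
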