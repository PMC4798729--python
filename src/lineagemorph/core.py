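"""Deterministic ODE models of feedback-regulated cell lineages.

A lineage is a chain of cell stages: stem cells (SC, population ``chi0``)
and/or committed progenitors (CP) feeding terminally differentiated cells
(TD).  At each division a proliferative cell self-renews with probability
``P`` or differentiates with probability ``1 - P``.  Diffusible factors
secreted by downstream stages feed back on ``P``: a saturating positive
(renewal-promoting) term with gain ``phi`` and a negative
(differentiation-promoting) term with gain ``gamma``.  Time ``tau`` is
measured in progenitor cell cycles throughout.

Two lineage architectures are covered:

* **Two-stage** (SC -> TD): ``dchi0/dtau = (2P - 1) chi0`` and
  ``dchi1/dtau = 2 (1 - P) chi0 - delta chi1``, with ``delta`` the TD
  turnover rate relative to the cell cycle.  ``delta = 0`` is the
  *final-state* system: TD cells never die, and the lineage freezes once
  the SC pool is exhausted.
* **Three-stage** (SC -> CP -> TD): SCs produce CPs at constant rate
  ``zeta``; all feedback targets the CP self-renewal probability.

The module provides the closed-form equilibria and bistability analysis of
the two-stage system, the growth-leap ("final-state") regime
classification, exogenous pulse experiments, and a qualitative behavior
census over feedback architectures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FeedbackForm",
    "PositiveSource",
    "FeedbackParams",
    "TwoStageParams",
    "ThreeStageParams",
    "LineageState",
    "LineageTrajectory",
    "EquilibriumSet",
    "CriticalValues",
    "RegimeLabel",
    "PulseSchedule",
    "renewal_probability",
    "two_stage_rhs",
    "three_stage_rhs",
    "integrate_lineage",
    "equilibria_two_stage",
    "bistability_threshold",
    "critical_values",
    "classify_final_state_regime",
    "apply_pulse_experiment",
    "behavior_census",
]

# Default solver tolerances (stiff-safe adaptive integration).
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
# "Final state reached" criterion: SC pool negligible and TD drift flat.
CONVERGENCE_CHI0 = 1e-8
CONVERGENCE_DCHI1 = 1e-10


class FeedbackForm(str, Enum):
    """How the positive and negative feedback terms combine into ``P``."""

    PRODUCT_HILL = "product_hill"
    SHARED_DENOMINATOR = "shared_denominator"


class PositiveSource(str, Enum):
    """Which stage's population drives the positive feedback term."""

    TD = "TD"
    SC = "SC"
    CP = "CP"


@dataclass(frozen=True)
class FeedbackParams:
    """Parameters of the self-renewal probability ``P``.

    product_hill:        P = p * (a / (1 + a)) * (1 / (1 + b))
    shared_denominator:  P = p * a / (1 + a + b)

    with ``a = phi * chi_pos + phi_ex`` and ``b = gamma * chi_neg +
    gamma_ex``.  The negative source is always the TD stage; the positive
    source defaults to TD for two-stage lineages and CP for three-stage
    lineages.
    """

    p: float
    phi: float
    gamma: float
    form: FeedbackForm = FeedbackForm.PRODUCT_HILL
    positive_source: PositiveSource = PositiveSource.TD
    phi_ex: float = 0.0
    gamma_ex: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must lie in (0, 1], got {self.p}")
        for name in ("phi", "gamma", "phi_ex", "gamma_ex"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TwoStageParams:
    """SC -> TD lineage; ``delta = d/v`` is the relative TD death rate."""

    feedback: FeedbackParams
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.delta < 0.0:
            raise ValueError("delta must be >= 0")


@dataclass(frozen=True)
class ThreeStageParams:
    """SC -> CP -> TD lineage with constant SC output.

    ``zeta`` is the SC proliferation rate relative to the CP cell cycle;
    feedback targets CP self-renewal with positive source CP and negative
    source TD.
    """

    feedback: FeedbackParams
    zeta: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.zeta < 0.0:
            raise ValueError("zeta must be >= 0")
        if self.delta < 0.0:
            raise ValueError("delta must be >= 0")


@dataclass(frozen=True)
class LineageState:
    """Stage populations ``chi`` at time ``tau`` (CP cell cycles)."""

    chi: np.ndarray
    tau: float = 0.0

    def __post_init__(self) -> None:
        chi = np.atleast_1d(np.asarray(self.chi, dtype=float))
        if chi.ndim != 1 or chi.size not in (2, 3):
            raise ValueError("state must hold 2 or 3 stage populations")
        if np.any(chi < 0.0):
            raise ValueError(f"populations must be nonnegative, got {chi}")
        object.__setattr__(self, "chi", chi)


@dataclass(frozen=True)
class LineageTrajectory:
    """Time series of stage populations and the renewal probability."""

    times: np.ndarray          # (n,) strictly increasing tau grid
    states: np.ndarray         # (n, n_stages)
    renewal: np.ndarray        # (n,) P(tau)

    @property
    def final_state(self) -> LineageState:
        return LineageState(chi=np.clip(self.states[-1], 0.0, None),
                            tau=float(self.times[-1]))

    def to_frame(self):
        """Columnar export: tau, chi0, chi1[, chi2], P."""
        import pandas as pd

        cols = {"tau": self.times}
        for i in range(self.states.shape[1]):
            cols[f"chi{i}"] = self.states[:, i]
        cols["P"] = self.renewal
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class EquilibriumSet:
    """Fixed points of the two-stage system in terms of ``chi1``.

    ``chi1_roots`` always contains the zero root first; the low (unstable)
    and high (stable) roots follow when they are real and positive.  At
    every non-zero equilibrium the renewal probability is exactly 1/2 and
    ``chi0 = delta * chi1``.
    """

    chi1_roots: tuple[float, ...]
    chi0_values: tuple[float, ...]
    stability: tuple[bool, ...]
    bistable: bool
    unbounded: bool = False  # gamma == 0 degenerate limit


@dataclass(frozen=True)
class CriticalValues:
    """Bounds of the growth-leap region of the final-state system.

    These are the two values of ``chi1`` at which ``dchi0/dtau`` changes
    sign; they coincide with the non-zero equilibria of the matching
    ``delta > 0`` system.
    """

    chi1_critlow: float
    chi1_crithigh: float


class RegimeLabel(str, Enum):
    REGIME1_TOO_MANY_TD = "regime1_too_many_TD"
    REGIME2_TOO_FEW_TD = "regime2_too_few_TD"
    REGIME3_GROWTH_LEAP = "regime3_growth_leap"


@dataclass(frozen=True)
class PulseSchedule:
    """Non-overlapping windows of exogenous feedback input.

    Each window is ``(t_start, t_end, phi_ex, gamma_ex)``; within it the
    exogenous amounts are added inside the corresponding Hill arguments.
    """

    windows: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        wins = tuple(tuple(float(v) for v in w) for w in self.windows)
        for t0, t1, pex, gex in wins:
            if not t0 < t1:
                raise ValueError("pulse window requires t_start < t_end")
            if pex < 0 or gex < 0:
                raise ValueError("exogenous inputs must be >= 0")
        for (a0, a1, *_), (b0, b1, *_) in zip(sorted(wins), sorted(wins)[1:]):
            if b0 < a1:
                raise ValueError("pulse windows must not overlap")
        object.__setattr__(self, "windows", wins)


# ---------------------------------------------------------------------------
# Renewal probability and right-hand sides
# ---------------------------------------------------------------------------

def _feedback_populations(chi: np.ndarray, fb: FeedbackParams):
    """Map the state vector onto (positive-source, negative-source) pops."""
    if len(chi) == 2:
        neg = chi[1]
        pos = chi[0] if fb.positive_source is PositiveSource.SC else chi[1]
    else:
        neg = chi[2]
        pos = {PositiveSource.SC: chi[0],
               PositiveSource.CP: chi[1],
               PositiveSource.TD: chi[2]}[fb.positive_source]
    return pos, neg


def renewal_probability(state: LineageState | np.ndarray,
                        fb: FeedbackParams) -> float:
    """Self-renewal probability ``P`` for the given populations.

    Guaranteed to lie in ``[0, p]``; vanishes with the positive-source
    population in the product_hill form.
    """
    chi = state.chi if isinstance(state, LineageState) else np.asarray(state, float)
    if np.any(chi < 0.0):
        raise ValueError("populations must be nonnegative")
    pos, neg = _feedback_populations(chi, fb)
    a = fb.phi * pos + fb.phi_ex
    b = fb.gamma * neg + fb.gamma_ex
    if fb.form is FeedbackForm.PRODUCT_HILL:
        return fb.p * (a / (1.0 + a)) / (1.0 + b)
    return fb.p * a / (1.0 + a + b)


def _renewal_raw(chi: np.ndarray, fb: FeedbackParams) -> float:
    # Unvalidated fast path used inside ODE right-hand sides, where the
    # solver may probe slightly negative populations.
    pos, neg = _feedback_populations(np.clip(chi, 0.0, None), fb)
    a = fb.phi * pos + fb.phi_ex
    b = fb.gamma * neg + fb.gamma_ex
    if fb.form is FeedbackForm.PRODUCT_HILL:
        return fb.p * (a / (1.0 + a)) / (1.0 + b)
    return fb.p * a / (1.0 + a + b)


def two_stage_rhs(state: LineageState | np.ndarray,
                  params: TwoStageParams) -> np.ndarray:
    """d(chi0, chi1)/dtau of the two-stage lineage."""
    chi = state.chi if isinstance(state, LineageState) else np.asarray(state, float)
    P = _renewal_raw(chi, params.feedback)
    return np.array([
        (2.0 * P - 1.0) * chi[0],
        2.0 * (1.0 - P) * chi[0] - params.delta * chi[1],
    ])


def three_stage_rhs(state: LineageState | np.ndarray,
                    params: ThreeStageParams) -> np.ndarray:
    """d(chi0, chi1, chi2)/dtau of the three-stage lineage.

    The SC pool is held constant (``dchi0/dtau = 0``); its output feeds the
    CP stage at rate ``zeta * chi0``.
    """
    chi = state.chi if isinstance(state, LineageState) else np.asarray(state, float)
    P = _renewal_raw(chi, params.feedback)
    return np.array([
        0.0,
        params.zeta * chi[0] + (2.0 * P - 1.0) * chi[1],
        2.0 * (1.0 - P) * chi[1] - params.delta * chi[2],
    ])


def _rhs_for(params) -> Callable[[float, np.ndarray], np.ndarray]:
    if isinstance(params, TwoStageParams):
        return lambda t, y: two_stage_rhs(y, params)
    if isinstance(params, ThreeStageParams):
        return lambda t, y: three_stage_rhs(y, params)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def _expected_dim(params) -> int:
    return 2 if isinstance(params, TwoStageParams) else 3


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def rk4_path(rhs: Callable[[float, np.ndarray], np.ndarray],
             y0: np.ndarray, t0: float, t1: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classical RK4; shared by the deterministic and ensemble
    integrators so that the zero-noise ensemble limit is bit-identical."""
    n = max(1, int(math.ceil((t1 - t0) / dt - 1e-12)))
    h = (t1 - t0) / n
    times = t0 + h * np.arange(n + 1)
    out = np.empty((n + 1, len(y0)))
    out[0] = y = np.asarray(y0, float)
    t = t0
    for i in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = rhs(t + 0.5 * h, y + 0.5 * h * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += h
        out[i + 1] = y
    return times, out


def integrate_lineage(params, init: LineageState, t_end: float,
                      *, rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                      t_eval: np.ndarray | None = None,
                      method: str = "LSODA",
                      dt: float = 0.01) -> LineageTrajectory:
    """Integrate a lineage ODE from ``init`` to ``t_end``.

    ``method`` may be any stiff-safe ``solve_ivp`` method, or ``"rk4"``
    for the fixed-step reference integrator (step ``dt``).

    Raises ``RuntimeError`` (with the failure time) if the solver fails.
    """
    if t_end <= init.tau:
        raise ValueError("t_end must exceed the initial time")
    if len(init.chi) != _expected_dim(params):
        raise ValueError("initial state dimension does not match the model")
    rhs = _rhs_for(params)
    if method == "rk4":
        times, states = rk4_path(rhs, init.chi, init.tau, t_end, dt)
        if t_eval is not None:
            states = np.column_stack([
                np.interp(t_eval, times, states[:, j])
                for j in range(states.shape[1])
            ])
            times = np.asarray(t_eval, float)
    else:
        sol = solve_ivp(rhs, (init.tau, t_end), init.chi, method=method,
                        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise RuntimeError(
                f"lineage integration failed at tau={sol.t[-1]:.6g}: {sol.message}")
        times, states = sol.t, sol.y.T
    states = np.clip(states, 0.0, None)
    fb = params.feedback
    renewal = np.array([_renewal_raw(s, fb) for s in states])
    return LineageTrajectory(times=times, states=states, renewal=renewal)


# ---------------------------------------------------------------------------
# Equilibria and bistability of the two-stage system
# ---------------------------------------------------------------------------

def equilibria_two_stage(params: TwoStageParams) -> EquilibriumSet:
    """Closed-form fixed points of the two-stage steady-state system.

    With the product_hill feedback, setting ``P = 1/2`` gives the quadratic
    ``gamma phi chi1^2 + (gamma + phi - 2 p phi) chi1 + 1 = 0`` whose real
    positive roots are the low (unstable) and high (stable) equilibria;
    the extinct state ``chi1 = 0`` is always a stable equilibrium.  Each
    non-zero root carries ``chi0 = delta * chi1``.

    Degenerate limits are reported rather than raised: ``gamma = 0`` yields
    only the zero root with ``unbounded=True`` (growth saturates at ``P ->
    p > 1/2`` and never equilibrates); ``phi = 0`` yields only the zero
    root (``P`` is identically 0 in the product form).
    """
    fb = params.feedback
    if fb.form is not FeedbackForm.PRODUCT_HILL or fb.positive_source is not PositiveSource.TD:
        return _equilibria_numeric(params)
    p, phi, gamma = fb.p, fb.phi, fb.gamma
    if phi == 0.0:
        return EquilibriumSet((0.0,), (0.0,), (True,), bistable=False)
    if gamma == 0.0:
        unbounded = p > 0.5
        roots: list[float] = [0.0]
        chi0s: list[float] = [0.0]
        stab: list[bool] = [True]
        if not unbounded and p != 0.5:
            # 2 p phi chi = 1 + phi chi has a positive root only if p > 1/2.
            pass
        return EquilibriumSet(tuple(roots), tuple(chi0s), tuple(stab),
                              bistable=False, unbounded=unbounded)
    b = gamma + phi - 2.0 * p * phi
    disc = b * b - 4.0 * gamma * phi
    roots = [0.0]
    stab = [True]
    if disc >= 0.0 and b < 0.0:
        sq = math.sqrt(disc)
        low = (-b - sq) / (2.0 * gamma * phi)
        high = (-b + sq) / (2.0 * gamma * phi)
        if low > 0.0:
            roots += [low, high]
            stab += [False, True]
    bistable = len(roots) == 3 and roots[1] < roots[2]
    chi0s = tuple(params.delta * r for r in roots)
    return EquilibriumSet(tuple(roots), chi0s, tuple(stab), bistable=bistable)


def _equilibria_numeric(params: TwoStageParams) -> EquilibriumSet:
    """Root-scan fallback for non-default feedback configurations."""
    fb = params.feedback

    def g(chi1: float) -> float:
        pos = chi1  # positive source SC at equilibrium: chi0 = delta*chi1
        if fb.positive_source is PositiveSource.SC:
            pos = params.delta * chi1
        a = fb.phi * pos + fb.phi_ex
        bb = fb.gamma * chi1 + fb.gamma_ex
        if fb.form is FeedbackForm.PRODUCT_HILL:
            P = fb.p * (a / (1.0 + a)) / (1.0 + bb)
        else:
            P = fb.p * a / (1.0 + a + bb)
        return P - 0.5

    grid = np.concatenate([[0.0], np.geomspace(1e-8, 1e8, 2000)])
    vals = np.array([g(c) for c in grid])
    roots = [0.0]
    stab = [True]
    from scipy.optimize import brentq
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0.0:
            r = brentq(g, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-14)
            if r > 0.0:
                roots.append(r)
                stab.append(vals[i] > 0.0)  # P crossing 1/2 downward: stable
    bistable = sum(stab) >= 2 and len(roots) >= 3
    chi0s = tuple(params.delta * r for r in roots)
    return EquilibriumSet(tuple(roots), chi0s, tuple(stab), bistable=bistable)


def bistability_threshold(p: float) -> float | None:
    """Minimal ``phi/gamma`` ratio admitting bistability, or None.

    Two real positive equilibria of the two-stage system exist iff
    ``r = phi/gamma`` exceeds ``r* = (2p + 1 + 2 sqrt(2p)) / (2p - 1)^2``,
    the larger root of ``(2p-1)^2 r^2 - (4p+2) r + 1 = 0``.  For ``p = 1``
    this is ``3 + 2 sqrt(2) ~ 5.83``.  Requires ``p > 0.5``; at or below
    that no ratio yields bistability and ``None`` is returned.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if p <= 0.5:
        return None
    a = 2.0 * p - 1.0
    return (2.0 * p + 1.0 + 2.0 * math.sqrt(2.0 * p)) / (a * a)


def critical_values(params: TwoStageParams) -> CriticalValues | None:
    """Growth-leap bounds of the final-state (``delta = 0``) system.

    Returns the two values of ``chi1`` at which ``dchi0/dtau`` changes
    sign, identical to the non-zero equilibria of the matching turnover
    system.  Returns ``None`` when the bistability condition is not met
    (no growth-leap region).
    """
    eq = equilibria_two_stage(replace(params, delta=1.0))
    if len(eq.chi1_roots) < 3:
        fb = params.feedback
        # Double-root boundary: exactly at threshold the two critical
        # values coincide.
        if fb.form is FeedbackForm.PRODUCT_HILL and fb.gamma > 0 and fb.phi > 0:
            b = fb.gamma + fb.phi - 2.0 * fb.p * fb.phi
            disc = b * b - 4.0 * fb.gamma * fb.phi
            if abs(disc) < 1e-12 and b < 0:
                r = -b / (2.0 * fb.gamma * fb.phi)
                return CriticalValues(r, r)
        return None
    return CriticalValues(eq.chi1_roots[1], eq.chi1_roots[2])


# ---------------------------------------------------------------------------
# Final-state regime classification
# ---------------------------------------------------------------------------

def integrate_to_final_state(params: TwoStageParams, init: LineageState,
                             *, max_time: float = 20000.0,
                             chunk: float = 200.0,
                             rtol: float = DEFAULT_RTOL,
                             atol: float = DEFAULT_ATOL) -> LineageTrajectory:
    """Integrate a ``delta = 0`` system until the SC pool is exhausted.

    Convergence: ``chi0 < 1e-8 * max(1, chi1)`` and ``|dchi1/dtau|`` below
    1e-10 across the last cell cycle.  Raises ``RuntimeError`` carrying the
    last state if ``max_time`` is reached first.
    """
    rhs = _rhs_for(params)
    t0 = init.tau
    y = init.chi.copy()
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    while t0 < init.tau + max_time:
        t1 = min(t0 + chunk, init.tau + max_time)
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed at tau={sol.t[-1]:.6g}")
        all_t.append(sol.t)
        all_y.append(sol.y.T)
        y = sol.y[:, -1]
        t0 = sol.t[-1]
        chi0, chi1 = max(y[0], 0.0), max(y[1], 0.0)
        d1 = abs(rhs(t0, y)[1])
        if chi0 < CONVERGENCE_CHI0 * max(1.0, chi1) and d1 < CONVERGENCE_DCHI1:
            break
    else:  # pragma: no cover - defensive
        pass
    if t0 >= init.tau + max_time:
        raise RuntimeError(
            f"no convergence within max_time={max_time}; last state {y}")
    times = np.concatenate(all_t)
    keep = np.concatenate([[True], np.diff(times) > 0])
    states = np.clip(np.vstack(all_y)[keep], 0.0, None)
    times = times[keep]
    fb = params.feedback
    renewal = np.array([_renewal_raw(s, fb) for s in states])
    return LineageTrajectory(times=times, states=states, renewal=renewal)


def classify_final_state_regime(init: LineageState,
                                params: TwoStageParams) -> RegimeLabel:
    """Classify a final-state trajectory against the growth-leap bounds.

    * regime 1 -- too many starting TD cells: ``chi1(0)`` already exceeds
      the upper critical value; the SC pool shrinks monotonically.
    * regime 2 -- too few TD cells: the SC pool is exhausted before
      ``chi1`` can climb past the lower critical value.
    * regime 3 -- growth leap: ``chi1`` enters the interval where the SC
      pool expands, and is carried past the upper critical value.
    """
    if params.delta != 0.0:
        raise ValueError("regime classification applies to delta = 0 systems")
    crit = critical_values(params)
    if crit is None:
        raise ValueError("bistability condition not met: no growth-leap region")
    if init.chi[1] > crit.chi1_crithigh:
        return RegimeLabel.REGIME1_TOO_MANY_TD
    if init.chi[0] == 0.0:
        return RegimeLabel.REGIME2_TOO_FEW_TD
    traj = integrate_to_final_state(params, init)
    chi1 = traj.states[:, 1]
    entered = np.any((chi1 > crit.chi1_critlow) & (chi1 < crit.chi1_crithigh))
    if (entered or init.chi[1] < crit.chi1_critlow) and chi1[-1] > crit.chi1_crithigh:
        return RegimeLabel.REGIME3_GROWTH_LEAP
    return RegimeLabel.REGIME2_TOO_FEW_TD


# ---------------------------------------------------------------------------
# Exogenous pulse experiments
# ---------------------------------------------------------------------------

def apply_pulse_experiment(params, init: LineageState,
                           schedule: PulseSchedule, t_end: float,
                           *, rtol: float = DEFAULT_RTOL,
                           atol: float = DEFAULT_ATOL,
                           points_per_cycle: int = 20) -> LineageTrajectory:
    """Integrate with transient exogenous feedback inputs.

    Within each schedule window the exogenous amounts are added inside the
    corresponding Hill arguments (positive term ``phi chi_pos + phi_ex``,
    negative denominator ``1 + gamma chi_neg + gamma_ex``); outside all
    windows dynamics revert to the endogenous form.
    """
    edges = {init.tau, t_end}
    for t0, t1, *_ in schedule.windows:
        edges.update((t0, t1))
    edges = sorted(t for t in edges if init.tau <= t <= t_end)
    y = init.chi.copy()
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for t0, t1 in zip(edges, edges[1:]):
        mid = 0.5 * (t0 + t1)
        pex = gex = 0.0
        for w0, w1, wp, wg in schedule.windows:
            if w0 <= mid < w1:
                pex, gex = wp, wg
        fb = replace(params.feedback, phi_ex=pex, gamma_ex=gex)
        seg_params = replace(params, feedback=fb)
        n = max(2, int(round((t1 - t0) * points_per_cycle)) + 1)
        seg = integrate_lineage(seg_params, LineageState(chi=y, tau=t0), t1,
                                rtol=rtol, atol=atol,
                                t_eval=np.linspace(t0, t1, n))
        ts.append(seg.times)
        ys.append(seg.states)
        y = seg.states[-1]
    times = np.concatenate(ts)
    states = np.vstack(ys)
    keep = np.concatenate([[True], np.diff(times) > 0])
    times, states = times[keep], states[keep]
    fb0 = params.feedback
    # report endogenous-plus-active-exogenous renewal along the path
    renewal = np.empty(len(times))
    for i, (t, s) in enumerate(zip(times, states)):
        pex = gex = 0.0
        for w0, w1, wp, wg in schedule.windows:
            if w0 <= t < w1:
                pex, gex = wp, wg
        renewal[i] = _renewal_raw(s, replace(fb0, phi_ex=pex, gamma_ex=gex))
    return LineageTrajectory(times=times, states=states, renewal=renewal)


# ---------------------------------------------------------------------------
# Behavior census (qualitative outcome table)
# ---------------------------------------------------------------------------

_DIVERGENCE_BOUND = 1e7


def _long_run_outcome(params: TwoStageParams, chi0_0: float, chi1_0: float,
                      t_end: float = 2000.0) -> str:
    """Long-run fate of one initial condition: zero / nonzero / unbounded."""
    rhs = _rhs_for(params)

    def blown(t, y):
        return max(y[0], y[1]) - _DIVERGENCE_BOUND
    blown.terminal = True
    blown.direction = 1.0

    sol = solve_ivp(rhs, (0.0, t_end), [chi0_0, chi1_0], method="LSODA",
                    rtol=1e-7, atol=1e-9, events=blown)
    y = np.clip(sol.y[:, -1], 0.0, None)
    if sol.status == 1 or max(y) > 0.5 * _DIVERGENCE_BOUND:
        return "unbounded"
    dy = rhs(sol.t[-1], y)
    growing = dy[0] > 1e-6 * max(1.0, y[0])
    if growing:
        return "unbounded"
    tol = 1e-4
    if params.delta > 0.0:
        return "zero" if y[1] < tol else "nonzero"
    # final-state system: zero means the lineage produced essentially nothing
    return "zero" if y[1] < tol else "nonzero"


def _renewal_sign_pattern(fb: FeedbackParams, chi_max: float) -> str:
    """Sign pattern of P(chi1) - 1/2 over chi1 in (0, chi_max], compressed.

    '-+-' indicates a bounded growth-leap window; '+' or '+-' means the
    extinct state is not protective (P starts above 1/2)."""
    grid = np.concatenate([[1e-12], np.geomspace(1e-9, chi_max, 4000)])
    signs = []
    for c in grid:
        P = _renewal_raw(np.array([0.0, c]), fb)
        s = "+" if P > 0.5 else "-"
        if not signs or signs[-1] != s:
            signs.append(s)
    return "".join(signs)


def behavior_census(form: FeedbackForm = FeedbackForm.PRODUCT_HILL,
                    *, p_values: Sequence[float] = (0.6, 0.75, 0.9),
                    t_end: float = 2000.0) -> dict:
    """Qualitative outcome table over feedback architectures.

    For each feedback configuration (none / negative only / positive only /
    both) and each turnover class (steady state ``delta > 0`` vs final
    state ``delta = 0``), parameter samples are integrated from a
    scale-aware grid of initial conditions.  Each cell of the resulting
    table is summarized as ``"Never"``, ``"Sometimes"`` or ``"Always"``
    across samples, for the outcome classes: reachable zero state,
    reachable stable non-zero state, unbounded growth, and bistability /
    bimodality (ultrasensitive switching with an extinction-capable slow
    mode, detected from the sign pattern of ``P - 1/2``).

    A lineage must be present: initial conditions always have
    ``chi0(0) > 0``.
    """
    rows = ("none", "neg", "pos", "both")
    table: dict[str, dict[str, dict[str, str]]] = {"steady": {}, "final": {}}
    for regime, delta in (("steady", 1.0), ("final", 0.0)):
        for row in rows:
            flags = {"zero": [], "nonzero": [], "unbounded": [], "bi": []}
            for p in p_values:
                for fb, scale in _census_feedback_samples(row, form, p):
                    params = TwoStageParams(feedback=fb, delta=delta)
                    outcomes = set()
                    chi1_grid = np.unique(np.concatenate(
                        [[0.0], np.geomspace(0.01, 4.0, 6)])) * scale
                    for c0 in (0.05, 1.0):
                        for c1 in chi1_grid:
                            outcomes.add(_long_run_outcome(params, c0, c1, t_end))
                    pattern = _renewal_sign_pattern(fb, 100.0 * scale)
                    if regime == "steady":
                        # bistable: stable extinct state coexists with a
                        # stable positive equilibrium (downward P crossing).
                        bi = pattern.startswith("-") and "+-" in pattern \
                            and "nonzero" in outcomes and "zero" in outcomes
                    else:
                        bi = pattern.startswith("-") and "+" in pattern
                    flags["zero"].append("zero" in outcomes)
                    flags["nonzero"].append("nonzero" in outcomes)
                    flags["unbounded"].append("unbounded" in outcomes)
                    flags["bi"].append(bi)
            table[regime][row] = {
                k: _summarize(v) for k, v in flags.items()}
    return table


def _census_feedback_samples(row: str, form: FeedbackForm, p: float):
    """Representative feedback parameter samples for one table row.

    Yields ``(FeedbackParams, chi1_scale)`` pairs; the scale sets the
    initial-condition sweep so that critical population sizes are probed.
    'none' is modeled as a constant renewal probability ``P = p``.
    """
    if row == "none":
        yield _ConstantRenewal(p), 1.0
        return
    if row == "neg":
        for gamma in (0.1, 1.0):
            fb = FeedbackParams(p=p, phi=0.0, gamma=gamma, form=form)
            # for the product form P=0 when phi=0; pure negative feedback
            # means the positive branch is absent, i.e. P = p/(1+gamma chi)
            yield _NegOnly(p, gamma), (2 * p - 1) / gamma
        return
    if row == "pos":
        for phi in (0.1, 1.0):
            fb = FeedbackParams(p=p, phi=phi, gamma=0.0, form=form)
            yield fb, 1.0 / (phi * (2 * p - 1))
        return
    # both
    rstar = bistability_threshold(p)
    for r in (0.5 * rstar, 3.0 * rstar):
        gamma = 0.05
        fb = FeedbackParams(p=p, phi=r * gamma, gamma=gamma, form=form)
        scale = 1.0 / gamma
        yield fb, scale


class _ConstantRenewal:
    """Feedback stub with P identically p (open-loop lineage)."""

    form = FeedbackForm.PRODUCT_HILL
    phi = 0.0
    gamma = 0.0
    phi_ex = 0.0
    gamma_ex = 0.0
    positive_source = PositiveSource.TD

    def __init__(self, p: float):
        self.p = p


class _NegOnly:
    """Feedback stub with P = p / (1 + gamma chi_neg) (no positive branch)."""

    form = FeedbackForm.PRODUCT_HILL
    phi_ex = 0.0
    gamma_ex = 0.0
    positive_source = PositiveSource.TD

    def __init__(self, p: float, gamma: float):
        self.p = p
        self.gamma = gamma
        self.phi = 0.0


def _summarize(hits: list[bool]) -> str:
    if all(hits):
        return "Always"
    if any(hits):
        return "Sometimes"
    return "Never"


# Dispatch on the stub classes inside the raw renewal evaluation.
_renewal_raw_dataclass = _renewal_raw


def _renewal_raw(chi: np.ndarray, fb) -> float:  # noqa: F811
    if isinstance(fb, _ConstantRenewal):
        return fb.p
    if isinstance(fb, _NegOnly):
        neg = max(chi[-1], 0.0)
        return fb.p / (1.0 + fb.gamma * neg)
    return _renewal_raw_dataclass(chi, fb)
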