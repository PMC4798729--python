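"""Constitutive physics of the 2D multiphase epithelium model.

The tissue is represented by smoothed volume fractions on a uniform
cell-centered Cartesian grid: committed progenitors ``chi1``, terminally
differentiated cells ``chi2``, a stem-cell band ``chi0`` pinned to the
basement membrane (BM), stroma ``chiS`` below the BM and interstitial
fluid ``chiL`` above the apical (AP) surface.  The fractions partition
unity pointwise.

Physics per time step:

* quasi-steady reaction-diffusion of the diffusible feedback factors
  ``F`` (renewal-promoting) and ``G`` (differentiation-promoting), with
  production by CP/TD cells, natural decay, cellular and stromal uptake,
  and optional exogenous Gaussian sources in the stroma;
* the CP self-renewal field ``p1`` built from ``[F]`` and ``[G]`` exactly
  as in the well-mixed lineage model;
* lineage source terms for the fractions;
* generalized Darcy mechanics: cell velocity
  ``u = -kappa (grad p - (lambda/eps) mu grad chiT)`` with the chemical
  potential ``mu = f'(chiT) - eps^2 lap chiT`` of a Cahn-Hilliard double
  well ``f = chi^2 (1-chi)^2 / 4``, and the pressure Poisson equation
  obtained from ``div u = Src_chiT``;
* conservative transport of the fractions by advection plus a
  generalized Fick flux ``J = -M chi grad mu``.

Boundary conditions: homogeneous Neumann for fractions and factors
(periodic in x optionally), homogeneous Dirichlet for pressure.  The
apical no-flux condition on the factors is imposed by the diffuse-domain
device of letting the diffusivity vanish in the fluid phase.

All operators are assembled as sparse matrices from matched
face/cell-difference stencils, so the discrete divergence of the velocity
equals the source field to linear-solver precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Grid2D",
    "FactorParams",
    "SpatialParams",
    "ExoSourceSpec",
    "FieldState",
    "self_renewal_field",
    "lineage_sources",
    "solve_quasi_steady_factor",
    "chemical_potential",
    "velocity_and_pressure",
    "advance_fractions",
    "stem_cell_layer",
    "exogenous_source",
    "adhesion_energy",
]

_CLIP_TOL = 0.1  # fraction over/undershoot tolerated and clipped per step


# ---------------------------------------------------------------------------
# Grid and discrete operators
# ---------------------------------------------------------------------------

def _d1_c2f(n: int, h: float, bc: str) -> sp.csr_matrix:
    """1D difference, cell values -> face gradients."""
    if bc == "periodic":
        rows, cols, vals = [], [], []
        for i in range(n):
            rows += [i, i]
            cols += [i, (i - 1) % n]
            vals += [1.0 / h, -1.0 / h]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    rows, cols, vals = [], [], []
    for i in range(1, n):
        rows += [i, i]
        cols += [i, i - 1]
        vals += [1.0 / h, -1.0 / h]
    if bc == "dirichlet0":
        rows += [0, n]
        cols += [0, n - 1]
        vals += [2.0 / h, -2.0 / h]
    elif bc != "neumann":
        raise ValueError(f"unknown bc {bc!r}")
    return sp.csr_matrix((vals, (rows, cols)), shape=(n + 1, n))


def _d1_f2c(n: int, h: float, bc: str) -> sp.csr_matrix:
    """1D divergence, face fluxes -> cell values."""
    if bc == "periodic":
        rows, cols, vals = [], [], []
        for i in range(n):
            rows += [i, i]
            cols += [(i + 1) % n, i]
            vals += [1.0 / h, -1.0 / h]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    rows, cols, vals = [], [], []
    for i in range(n):
        rows += [i, i]
        cols += [i + 1, i]
        vals += [1.0 / h, -1.0 / h]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n + 1))


def _avg_c2f(n: int, bc: str) -> sp.csr_matrix:
    """1D arithmetic average, cells -> faces (edge faces copy the edge cell)."""
    if bc == "periodic":
        rows, cols, vals = [], [], []
        for i in range(n):
            rows += [i, i]
            cols += [i, (i - 1) % n]
            vals += [0.5, 0.5]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    rows, cols, vals = [0, n], [0, n - 1], [1.0, 1.0]
    for i in range(1, n):
        rows += [i, i]
        cols += [i, i - 1]
        vals += [0.5, 0.5]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n + 1, n))


def _take_c2f(n: int, bc: str, side: str) -> sp.csr_matrix:
    """1D neighbor pick, cells -> faces, for upwinding (outside value 0)."""
    rows, cols, vals = [], [], []
    if bc == "periodic":
        for i in range(n):
            rows.append(i)
            cols.append((i - 1) % n if side == "left" else i)
            vals.append(1.0)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    for i in range(n + 1):
        j = i - 1 if side == "left" else i
        if 0 <= j < n:
            rows.append(i)
            cols.append(j)
            vals.append(1.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n + 1, n))


@dataclass(frozen=True)
class Grid2D:
    """Uniform cell-centered rectangular grid.

    The default domain matches the computational box used throughout the
    spatial scenarios, ``[-20, 20] x [-10, 10]``.  Arrays are shaped
    ``(ny, nx)``.
    """

    x0: float = -20.0
    x1: float = 20.0
    y0: float = -10.0
    y1: float = 10.0
    nx: int = 128
    ny: int = 64
    periodic_x: bool = False

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError("nx, ny must be >= 16")
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("degenerate domain")

    @property
    def dx(self) -> float:
        return (self.x1 - self.x0) / self.nx

    @property
    def dy(self) -> float:
        return (self.y1 - self.y0) / self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def x(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.dy

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def integrate(self, f: np.ndarray) -> float:
        return float(np.sum(f) * self.cell_area)

    # -- operator bundle ----------------------------------------------------

    def _xbc(self, bc: str) -> str:
        return "periodic" if self.periodic_x else bc

    @property
    def ops(self) -> "_Operators":
        return _operators_for(self)


class _Operators:
    """Sparse operator bundle for one grid (built once, cached)."""

    def __init__(self, g: Grid2D):
        Ix, Iy = sp.identity(g.nx, format="csr"), sp.identity(g.ny, format="csr")
        xbc_n, ybc_n = g._xbc("neumann"), "neumann"
        xbc_d, ybc_d = g._xbc("dirichlet0"), "dirichlet0"

        def kx(op):
            return sp.kron(Iy, op, format="csr")

        def ky(op):
            return sp.kron(op, Ix, format="csr")

        # gradients cells -> faces
        self.Gx_n = kx(_d1_c2f(g.nx, g.dx, xbc_n))
        self.Gy_n = ky(_d1_c2f(g.ny, g.dy, ybc_n))
        self.Gx_d = kx(_d1_c2f(g.nx, g.dx, xbc_d))
        self.Gy_d = ky(_d1_c2f(g.ny, g.dy, ybc_d))
        # divergence faces -> cells
        self.Dx = kx(_d1_f2c(g.nx, g.dx, g._xbc("none") if g.periodic_x else "none"))
        self.Dy = ky(_d1_f2c(g.ny, g.dy, "none"))
        # averages and upwind picks
        self.Ax = kx(_avg_c2f(g.nx, xbc_n))
        self.Ay = ky(_avg_c2f(g.ny, ybc_n))
        self.Lx_pick = kx(_take_c2f(g.nx, xbc_n, "left"))
        self.Rx_pick = kx(_take_c2f(g.nx, xbc_n, "right"))
        self.Ly_pick = ky(_take_c2f(g.ny, ybc_n, "left"))
        self.Ry_pick = ky(_take_c2f(g.ny, ybc_n, "right"))
        # Laplacians
        self.L_neu = (self.Dx @ self.Gx_n + self.Dy @ self.Gy_n).tocsr()
        self.L_dir = (self.Dx @ self.Gx_d + self.Dy @ self.Gy_d).tocsr()
        self._lu_cache: dict = {}
        self._grid = g

    def lap_neumann(self, f: np.ndarray) -> np.ndarray:
        return (self.L_neu @ f.ravel()).reshape(f.shape)

    def divergence(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        g = self._grid
        return (self.Dx @ fx.ravel() + self.Dy @ fy.ravel()).reshape(g.shape)

    def lu(self, key, build):
        if key not in self._lu_cache:
            self._lu_cache[key] = spla.splu(build().tocsc())
        return self._lu_cache[key]


_OPERATOR_CACHE: dict[Grid2D, _Operators] = {}


def _operators_for(g: Grid2D) -> _Operators:
    if g not in _OPERATOR_CACHE:
        _OPERATOR_CACHE[g] = _Operators(g)
    return _OPERATOR_CACHE[g]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorParams:
    """Reaction-diffusion coefficients of one diffusible factor.

    ``s1``/``s2`` are production rates from CP/TD cells, ``d0`` the natural
    decay rate, ``u1`` the uptake rate by CPs, and ``u_stroma`` the uptake
    rate in the stroma (nonzero only for the negative factor in the
    fingering scenarios).  The characteristic in-tissue decay length is
    ``sqrt(D / (d0 + u1))``.
    """

    D: float = 1.0
    s1: float = 0.0
    s2: float = 0.0
    d0: float = 0.1
    u1: float = 0.0
    u_stroma: float = 0.0

    def __post_init__(self) -> None:
        if min(self.D, self.s1, self.s2, self.d0, self.u1, self.u_stroma) < 0:
            raise ValueError("factor rates must be >= 0")

    @property
    def decay_length(self) -> float:
        k = self.d0 + self.u1
        if k <= 0:
            raise ValueError("decay length undefined without uptake/decay")
        return math.sqrt(self.D / k)


@dataclass(frozen=True)
class SpatialParams:
    """Dimensionless parameters of the continuum model."""

    v0: float = 1.0            # SC division rate (CP cycles^-1)
    v1: float = 1.0            # CP division rate
    d: float = 0.2             # TD death rate
    p1_min: float = 0.1        # self-renewal bounds
    p1_max: float = 1.0
    phi: float = 3.0           # positive feedback gain on [F]
    gamma: float = 5.0         # negative feedback gain on [G]
    factor_F: FactorParams = field(default_factory=lambda: FactorParams(
        D=1.0, s1=0.5, d0=0.1))
    factor_G: FactorParams = field(default_factory=lambda: FactorParams(
        D=1.0, s2=0.5, d0=0.1))
    kappa: float = 1.0         # cell motility in the Darcy law
    lam_BM: float = 0.2        # surface tension, BM side
    lam_AP: float = 0.2        # surface tension, AP side
    eps: float = 0.4           # interface thickness
    M: float = 0.05            # Fickian flux mobility
    sc_mass: float = 4.0       # conserved stem-cell integral (BM band)

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if not 0.0 <= self.p1_min <= self.p1_max <= 1.0:
            raise ValueError("require 0 <= p1_min <= p1_max <= 1")
        for name in ("v0", "v1", "d", "phi", "gamma", "kappa",
                     "lam_BM", "lam_AP", "M", "sc_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ExoSourceSpec:
    """Exogenous Gaussian source of a factor, produced in the stroma.

    The target concentration field is
    ``A = M * exp(-(x - cx)^2 / w - (y - y_C - cy)^2 / w)`` with ``y_C``
    the leftmost BM height (tracked dynamically) and ``w`` the squared
    Gaussian width (10 for F, 50 for G).  Production is the relaxation
    term ``alpha (A - C) chiS``, active for ``t_start <= T <= t_end``.
    """

    factor: Literal["F", "G"]
    magnitude: float = 1.0
    alpha: float = 1.0
    center_x: float = -20.0
    center_dy: float = 1.0
    width2: float | None = None
    t_start: float = 0.0
    t_end: float = math.inf

    def __post_init__(self) -> None:
        if self.magnitude < 0 or self.alpha < 0:
            raise ValueError("magnitude and alpha must be >= 0")
        if not self.t_start < self.t_end:
            raise ValueError("active window requires t_start < t_end")
        if self.width2 is None:
            object.__setattr__(self, "width2",
                               10.0 if self.factor == "F" else 50.0)

    def active(self, T: float) -> bool:
        return self.t_start <= T <= self.t_end

    def target_field(self, grid: Grid2D, y_C: float) -> np.ndarray:
        X, Y = grid.meshgrid()
        return self.magnitude * np.exp(
            -(X - self.center_x) ** 2 / self.width2
            - (Y - y_C - self.center_dy) ** 2 / self.width2)


@dataclass
class FieldState:
    """All fields of the continuum model at one instant."""

    grid: Grid2D
    chi1: np.ndarray
    chi2: np.ndarray
    chiS: np.ndarray
    chi0: np.ndarray | None = None
    F: np.ndarray | None = None
    G: np.ndarray | None = None
    pressure: np.ndarray | None = None
    mu: np.ndarray | None = None
    ux: np.ndarray | None = None   # cell-centered velocity components
    uy: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.chi0 is None:
            self.chi0 = np.zeros(self.grid.shape)

    @property
    def chi_bulk(self) -> np.ndarray:
        """Bulk epithelium volume fraction (CP + TD).

        The SC band ``chi0`` is a surface density pinned to the BM (the
        sharp-interface limit ``A(t) delta_BM``); it does not occupy bulk
        volume and is excluded from the partition of unity.
        """
        return self.chi1 + self.chi2

    @property
    def chiT(self) -> np.ndarray:
        """Epithelium fraction including the SC surface band (reporting)."""
        return self.chi0 + self.chi1 + self.chi2

    @property
    def chiL(self) -> np.ndarray:
        """Fluid fraction, closing the partition of unity over bulk phases."""
        return 1.0 - self.chi_bulk - self.chiS

    def partition_residual(self) -> float:
        # chiL is defined by closure; the meaningful residual is how far
        # any fraction strays outside [0, 1].
        worst = 0.0
        for f in (self.chi1, self.chi2, self.chiS, self.chiL, self.chiT):
            worst = max(worst, float(np.max(-f, initial=0.0)),
                        float(np.max(f - 1.0, initial=0.0)))
        return worst

    def copy(self) -> "FieldState":
        return FieldState(
            grid=self.grid,
            chi1=self.chi1.copy(), chi2=self.chi2.copy(),
            chiS=self.chiS.copy(), chi0=self.chi0.copy(),
            F=None if self.F is None else self.F.copy(),
            G=None if self.G is None else self.G.copy(),
            pressure=None if self.pressure is None else self.pressure.copy(),
            mu=None if self.mu is None else self.mu.copy(),
            ux=None if self.ux is None else self.ux.copy(),
            uy=None if self.uy is None else self.uy.copy(),
            time=self.time)


# ---------------------------------------------------------------------------
# Feedback and sources
# ---------------------------------------------------------------------------

def self_renewal_field(F: np.ndarray, G: np.ndarray,
                       params: SpatialParams) -> np.ndarray:
    """CP self-renewal probability field.

    ``p1 = p1_min + (p1_max - p1_min) * (phi F / (1 + phi F)) / (1 + gamma G)``
    """
    if np.any(F < 0) or np.any(G < 0):
        raise ValueError("factor concentrations must be nonnegative")
    a = params.phi * F
    return params.p1_min + (params.p1_max - params.p1_min) \
        * (a / (1.0 + a)) / (1.0 + params.gamma * G)


def lineage_sources(chi0: np.ndarray, chi1: np.ndarray, chi2: np.ndarray,
                    p1: np.ndarray, params: SpatialParams):
    """Net proliferation/differentiation/death sources of the fractions.

    ``Src_chi1 = v0 chi0 + v1 (2 p1 - 1) chi1``;
    ``Src_chi2 = 2 v1 (1 - p1) chi1 - d chi2``.  The SC band has no net
    source (SCs renew with probability 1/2 and are replenished through the
    BM constraint), so ``Src_chiT = Src_chi1 + Src_chi2``.
    """
    src1 = params.v0 * chi0 + params.v1 * (2.0 * p1 - 1.0) * chi1
    src2 = 2.0 * params.v1 * (1.0 - p1) * chi1 - params.d * chi2
    return src1, src2, src1 + src2


def exogenous_source(spec: ExoSourceSpec | None, chiS: np.ndarray,
                     grid: Grid2D, y_C: float, T: float,
                     u_stroma: float = 0.0):
    """Exogenous production/removal contributions of one factor.

    Returns ``(extra_removal, extra_source)`` fields entering the
    quasi-steady equation as ``... - extra_removal * C + extra_source``.
    The persistent stromal uptake ``-u_stroma [C] chiS`` is always
    applied; the relaxation production ``alpha (A - [C]) chiS`` only
    within the active window.
    """
    removal = u_stroma * chiS
    source = np.zeros(grid.shape)
    if spec is not None and spec.active(T):
        A = spec.target_field(grid, y_C)
        removal = removal + spec.alpha * chiS
        source = source + spec.alpha * A * chiS
    return removal, source


# ---------------------------------------------------------------------------
# Quasi-steady factor solve
# ---------------------------------------------------------------------------

def solve_quasi_steady_factor(grid: Grid2D, chi1: np.ndarray,
                              chi2: np.ndarray, chiL: np.ndarray,
                              fp: FactorParams,
                              extra_removal: np.ndarray | float = 0.0,
                              extra_source: np.ndarray | float = 0.0,
                              tol: float = 1e-10) -> np.ndarray:
    """Solve ``0 = div(D_eff grad C) + src - removal C`` for one factor.

    ``D_eff = D (1 - chiL)`` vanishes in the fluid phase, which imposes
    the apical no-flux condition in the diffuse-domain sense while leaving
    the basal (stromal) side freely diffusing.  ``removal = d0 + u1 chi1 +
    extra_removal`` must be strictly positive somewhere (it is, since
    ``d0 > 0`` in all scenarios).  The discrete system is an M-matrix, so
    the solution is nonnegative for nonnegative sources.
    """
    ops = grid.ops
    # small floor keeps the operator nonsingular where the fluid dominates
    d_eff = fp.D * np.clip(1.0 - chiL, 1e-6, None)
    dfx = ops.Ax @ d_eff.ravel()
    dfy = ops.Ay @ d_eff.ravel()
    A = (ops.Dx @ sp.diags(dfx) @ ops.Gx_n
         + ops.Dy @ sp.diags(dfy) @ ops.Gy_n)
    removal = fp.d0 + fp.u1 * chi1 + np.broadcast_to(
        np.asarray(extra_removal, float), grid.shape)
    A = A - sp.diags(removal.ravel())
    src = fp.s1 * chi1 + fp.s2 * chi2 + np.broadcast_to(
        np.asarray(extra_source, float), grid.shape)
    rhs = -src.ravel()
    C = spla.spsolve(A.tocsr(), rhs)
    res = np.linalg.norm(A @ C - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and res > 1e-8 * scale:
        raise RuntimeError(
            f"factor solve residual {res:.3e} exceeds tolerance "
            f"(rhs norm {scale:.3e})")
    C = C.reshape(grid.shape)
    return np.clip(C, 0.0, None)


# ---------------------------------------------------------------------------
# Mechanics
# ---------------------------------------------------------------------------

def double_well(chi: np.ndarray) -> np.ndarray:
    return 0.25 * chi ** 2 * (1.0 - chi) ** 2


def double_well_prime(chi: np.ndarray) -> np.ndarray:
    return 0.5 * chi * (1.0 - chi) * (1.0 - 2.0 * chi)


def chemical_potential(chiT: np.ndarray, grid: Grid2D,
                       params: SpatialParams) -> np.ndarray:
    """``mu = f'(chiT) - eps^2 lap chiT`` (Neumann Laplacian)."""
    return double_well_prime(chiT) - params.eps ** 2 * grid.ops.lap_neumann(chiT)


def _lambda_face(state_chiS: np.ndarray, chiL: np.ndarray, grid: Grid2D,
                 params: SpatialParams):
    """Surface tension on faces, blending BM and AP values by which
    non-epithelial phase is locally dominant."""
    if params.lam_BM == params.lam_AP:
        lam = np.full(grid.shape, params.lam_BM)
    else:
        denom = state_chiS + chiL
        w = np.where(denom > 1e-9, state_chiS / np.clip(denom, 1e-9, None), 0.5)
        lam = params.lam_AP + (params.lam_BM - params.lam_AP) * w
    ops = grid.ops
    return ops.Ax @ lam.ravel(), ops.Ay @ lam.ravel()


def velocity_and_pressure(src_chiT: np.ndarray, mu: np.ndarray,
                          chiT: np.ndarray, grid: Grid2D,
                          params: SpatialParams,
                          chiS: np.ndarray | None = None):
    """Solve the Darcy pressure equation and evaluate face velocities.

    ``-div(kappa grad p) = Src_chiT - div(kappa (lambda/eps) mu grad chiT)``
    with homogeneous Dirichlet pressure on the outer boundary, then
    ``u = -kappa (grad p - (lambda/eps) mu grad chiT)``.

    Returns ``(p, (ufx, ufy))`` with the velocity on x/y faces; the
    discrete face divergence of ``u`` reproduces ``src_chiT`` to solver
    precision by construction.
    """
    ops = grid.ops
    kappa = params.kappa
    if chiS is None:
        chiS = np.zeros(grid.shape)
    lam_fx, lam_fy = _lambda_face(chiS, 1.0 - chiT - chiS, grid, params)
    mu_fx = ops.Ax @ mu.ravel()
    mu_fy = ops.Ay @ mu.ravel()
    gx_chi = ops.Gx_n @ chiT.ravel()
    gy_chi = ops.Gy_n @ chiT.ravel()
    adh_x = kappa * (lam_fx / params.eps) * mu_fx * gx_chi
    adh_y = kappa * (lam_fy / params.eps) * mu_fy * gy_chi
    rhs = src_chiT.ravel() - (ops.Dx @ adh_x + ops.Dy @ adh_y)

    def build():
        return (-kappa * (ops.Dx @ ops.Gx_d + ops.Dy @ ops.Gy_d))

    lu = ops.lu(("pressure", kappa), build)
    p = lu.solve(rhs)
    # adh_x/adh_y already carry the kappa factor
    ufx = -kappa * (ops.Gx_d @ p) + adh_x
    ufy = -kappa * (ops.Gy_d @ p) + adh_y
    return p.reshape(grid.shape), (ufx, ufy)


def adhesion_energy(chiT: np.ndarray, grid: Grid2D,
                    params: SpatialParams) -> float:
    """``E = (1/eps) int lambda (f(chiT) + eps^2/2 |grad chiT|^2)``.

    Non-increasing in the absence of net sources; approximately
    ``lambda_BM L_BM + lambda_AP L_AP`` for well-resolved interfaces.
    """
    ops = grid.ops
    lam = 0.5 * (params.lam_BM + params.lam_AP)
    gx = ops.Gx_n @ chiT.ravel()
    gy = ops.Gy_n @ chiT.ravel()
    # face-based gradient energy: the exact discrete Lyapunov functional
    # of the matched gradient/divergence stencils (its variational
    # derivative is the mu used by the transport fluxes)
    well = double_well(chiT).sum() * grid.cell_area
    grad2 = (np.sum(gx ** 2) + np.sum(gy ** 2)) * grid.cell_area
    return lam / params.eps * (well + 0.5 * params.eps ** 2 * grad2)


# ---------------------------------------------------------------------------
# Transport
# ---------------------------------------------------------------------------

def _upwind_face_values(chi: np.ndarray, ufx: np.ndarray, ufy: np.ndarray,
                        grid: Grid2D):
    ops = grid.ops
    c = chi.ravel()
    lx, rx = ops.Lx_pick @ c, ops.Rx_pick @ c
    ly, ry = ops.Ly_pick @ c, ops.Ry_pick @ c
    cx = np.where(ufx > 0.0, lx, rx)
    cy = np.where(ufy > 0.0, ly, ry)
    return cx, cy


def advance_fractions(state: FieldState, dt: float, params: SpatialParams,
                      src1: np.ndarray, src2: np.ndarray,
                      mu: np.ndarray, ufx: np.ndarray, ufy: np.ndarray,
                      *, implicit_smoothing: bool = True) -> FieldState:
    """One conservative transport update of ``chi1, chi2, chiS``.

    Advection (upwind) and the lineage sources are explicit; the
    Cahn-Hilliard flux ``J = -M chi grad mu`` is explicit with a
    constant-coefficient biharmonic stabilization solved implicitly, which
    lifts the fourth-order explicit step restriction.  The fluid fraction
    closes the partition of unity identically.

    Raises ``FloatingPointError`` if fractions leave ``[0, 1]`` by more
    than the clip tolerance (the step should then be retried with a
    smaller ``dt``).
    """
    grid = state.grid
    ops = grid.ops
    gmu_x = ops.Gx_n @ mu.ravel()
    gmu_y = ops.Gy_n @ mu.ravel()
    chiT = state.chi_bulk
    chiT_fx = ops.Ax @ chiT.ravel()
    chiT_fy = ops.Ay @ chiT.ravel()

    # fraction of the returning flux carried by the stroma phase
    chiL = state.chiL
    denom = state.chiS + chiL
    wS = np.where(denom > 1e-6, state.chiS / np.clip(denom, 1e-6, None), 0.0)
    wS_fx = ops.Ax @ wS.ravel()
    wS_fy = ops.Ay @ wS.ravel()

    def ch_flux(chi_field, sign=+1.0, weight_fx=None, weight_fy=None):
        if weight_fx is None:
            fx = ops.Ax @ chi_field.ravel()
            fy = ops.Ay @ chi_field.ravel()
        else:
            fx, fy = weight_fx, weight_fy
        jx = -params.M * fx * gmu_x * sign
        jy = -params.M * fy * gmu_y * sign
        return jx, jy

    updates = {}
    for name, chi_field, src in (("chi1", state.chi1, src1),
                                 ("chi2", state.chi2, src2)):
        jx, jy = ch_flux(chi_field)
        ax, ay = _upwind_face_values(chi_field, ufx, ufy, grid)
        div_total = ops.Dx @ (jx + ufx * ax) + ops.Dy @ (jy + ufy * ay)
        updates[name] = chi_field + dt * (
            -div_total.reshape(grid.shape) + src)

    # stroma: J_S = -w_S J_T (the NE phases absorb the returning CH flux)
    jTx = -params.M * chiT_fx * gmu_x
    jTy = -params.M * chiT_fy * gmu_y
    jSx, jSy = -wS_fx * jTx, -wS_fy * jTy
    axS, ayS = _upwind_face_values(state.chiS, ufx, ufy, grid)
    divS = ops.Dx @ (jSx + ufx * axS) + ops.Dy @ (jSy + ufy * ayS)
    chiS_new = state.chiS - dt * divS.reshape(grid.shape)

    if implicit_smoothing and params.M > 0:
        # first-order splitting: the stiff constant-coefficient biharmonic
        # is added explicitly at the old state and subtracted implicitly at
        # the new one, damping the fourth-order step restriction
        key = ("ch_smooth", dt, params.M, params.eps)
        c = dt * params.M * params.eps ** 2

        def build():
            L2 = (ops.L_neu @ ops.L_neu).tocsc()
            return (sp.identity(grid.n_cells, format="csc") + c * L2)

        lu = ops.lu(key, build)
        for name, old in (("chi1", state.chi1), ("chi2", state.chi2)):
            fstar = updates[name].ravel() \
                + c * (ops.L_neu @ (ops.L_neu @ old.ravel()))
            updates[name] = lu.solve(fstar).reshape(grid.shape)
        fstar = chiS_new.ravel() \
            + c * (ops.L_neu @ (ops.L_neu @ state.chiS.ravel()))
        chiS_new = lu.solve(fstar).reshape(grid.shape)

    new = state.copy()
    new.chi1, new.chi2, new.chiS = updates["chi1"], updates["chi2"], chiS_new
    new.time = state.time + dt
    viol = new.partition_residual()
    if not np.isfinite(viol) or viol > _CLIP_TOL:
        raise FloatingPointError(
            f"fraction bounds violated by {viol:.3e} at T={new.time:.4f}")
    for f in (new.chi1, new.chi2, new.chiS):
        np.clip(f, 0.0, 1.0, out=f)
    return new


# ---------------------------------------------------------------------------
# Stem-cell layer
# ---------------------------------------------------------------------------

def stem_cell_layer(chi_bulk: np.ndarray, chiS: np.ndarray, grid: Grid2D,
                    params: SpatialParams,
                    target_mass: float | None = None) -> np.ndarray:
    """SC band pinned to the basement membrane.

    The band indicator ``b = chi_bulk * chiS`` is supported on the
    epithelium-stroma interface over a width of order ``eps``; the
    amplitude ``A(t)`` is renormalized every step so that the SC integral
    stays at ``target_mass`` (default ``params.sc_mass``) no matter how the
    BM deforms or lengthens.

    Raises ``RuntimeError`` when no BM interface can be found (the
    epithelium has vanished or detached from the stroma).
    """
    if target_mass is None:
        target_mass = params.sc_mass
    band = chi_bulk * chiS
    total = grid.integrate(band)
    if total < 1e-8:
        raise RuntimeError("no basement membrane found: epithelium vanished")
    return (target_mass / total) * band
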