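"""Time-accurate 2D incompressible Navier-Stokes on the staggered grid.

Finite-volume discretization on the stair-step channel defined by a
:class:`~umiflow.geometry.Grid2D`:

- ``u`` (axial velocity) on x-faces, shape ``(ny, nx+1)``;
- ``v`` (depth velocity) on y-faces, shape ``(ny+1, nx)``;
- ``p`` (relative pressure) at cell centers, shape ``(ny, nx)``.

Convection uses first-order upwind in the implicit operator stabilised by a
deferred-correction QUICK term (quadratic upstream-biased interpolation);
diffusion is central; the time derivative is a second-order implicit
backward scheme (BDF2, backward Euler on the first step).  Pressure-velocity
coupling is a SIMPLE-family iteration: implicit momentum predictor (which
carries any body force, so forcing survives into the pressure source), then
a pressure-correction Poisson assembled from the momentum diagonal.

Boundary conditions: prescribed inlet profile (parabolic by default) on the
upstream boundary, no-slip on the stair-step walls (half-cell linear flux),
and a "free-flow" outlet: zero streamwise velocity gradient with an additive
global mass correction so inlet and outlet fluxes match exactly.

Linear systems are solved with scipy's sparse direct solver; the converged
field is solver-independent to within the residual tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from umiflow.geometry import Grid2D


class ConvergenceError(RuntimeError):
    """Raised when the outer (SIMPLE) iteration fails to converge."""

    def __init__(self, message: str, history: list):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid: density (kg/m^3) and dynamic viscosity (Pa s)."""

    rho: float = 1.0e3
    mu: float = 4.0e-3

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


def parabolic_profile(y_rel: np.ndarray) -> np.ndarray:
    """Plane-Poiseuille shape with unit mean over (0,1): 6 y (1 - y)."""
    return 6.0 * y_rel * (1.0 - y_rel)


@dataclass(frozen=True)
class BoundaryCondition:
    """Inlet mean velocity with a profile shape across the local lumen.

    ``profile`` maps relative depth in (0, 1) to a shape function; it is
    renormalised so the *discrete* inlet flux equals
    ``inlet_mean_velocity * lumen height`` exactly.  Outlet is free-flow,
    walls no-slip (fixed by the discretization, not configurable).
    """

    inlet_mean_velocity: float
    profile: Callable[[np.ndarray], np.ndarray] = parabolic_profile

    def inlet_values(self, grid: Grid2D) -> np.ndarray:
        """Discrete inlet u at fluid rows of column 0 (shape (n_rows,))."""
        lo, hi = grid.wall_lower_y[0], grid.wall_upper_y[0]
        n = hi - lo + 1
        y_rel = (np.arange(n) + 0.5) / n
        shape = np.asarray(self.profile(y_rel), dtype=float)
        mean = shape.mean()
        if abs(mean) < 1e-300:
            return np.zeros(n)
        return self.inlet_mean_velocity * shape / mean


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls.

    ``dt`` defaults to the color-Doppler frame interval 29.075 ms
    (34.394 Hz).  ``residual_tol`` is the non-dimensional residual target
    for momentum and continuity (1e-2 default); under-relaxation factors
    are conventional SIMPLE values.
    """

    dt: float = 0.029075
    residual_tol: float = 1.0e-2
    max_outer_iters: int = 300
    alpha_u: float = 0.7
    alpha_p: float = 0.3
    convection_scheme: str = "quick"  # "quick" | "upwind"
    u_char: float = 0.1

    def __post_init__(self):
        if self.dt <= 0 or self.residual_tol <= 0:
            raise ValueError("dt and residual_tol must be positive")
        if self.convection_scheme not in ("quick", "upwind"):
            raise ValueError("convection_scheme must be 'quick' or 'upwind'")


@dataclass
class FlowField:
    """Staggered velocity/pressure state at one time level (SI units)."""

    u: np.ndarray  # (ny, nx+1)
    v: np.ndarray  # (ny+1, nx)
    p: np.ndarray  # (ny, nx)
    t: float = 0.0

    def copy(self) -> "FlowField":
        return FlowField(self.u.copy(), self.v.copy(), self.p.copy(), self.t)

    @staticmethod
    def zeros(grid: Grid2D, t: float = 0.0) -> "FlowField":
        return FlowField(
            np.zeros((grid.ny, grid.nx + 1)),
            np.zeros((grid.ny + 1, grid.nx)),
            np.zeros((grid.ny, grid.nx)),
            t,
        )


@dataclass
class FeedbackTerm:
    """Implicit Doppler-feedback forcing for the momentum equations.

    ``gain`` is the dimensional gain K_v* rho U / L (N/m^3 per m/s of
    Doppler mismatch), cell-centered and already masked to the feedback
    domain (zero elsewhere); ``beam`` the unit beam vector (ex, ey);
    ``vm`` the measured Doppler velocity on the computational cell centers.
    On convergence of the outer iteration the resulting force equals the
    explicit feedback formula f = -gain (V_c - V_m) e.
    """

    gain: np.ndarray  # (ny, nx)
    beam: np.ndarray  # (2,)
    vm: np.ndarray  # (ny, nx)


# ---------------------------------------------------------------------------
# internals


class _Stencil:
    """Precomputed masks and index maps for one grid (cached per Grid2D)."""

    def __init__(self, grid: Grid2D):
        self.grid = grid
        ny, nx = grid.ny, grid.nx
        fluid = grid.fluid

        mu = np.zeros((ny, nx + 1), dtype=bool)
        mu[:, 1:nx] = fluid[:, : nx - 1] & fluid[:, 1:]
        self.mask_u_unknown = mu
        self.mask_u_inlet = np.zeros((ny, nx + 1), dtype=bool)
        self.mask_u_inlet[:, 0] = fluid[:, 0]
        self.mask_u_outlet = np.zeros((ny, nx + 1), dtype=bool)
        self.mask_u_outlet[:, nx] = fluid[:, nx - 1]
        self.active_u = mu | self.mask_u_inlet | self.mask_u_outlet

        mv = np.zeros((ny + 1, nx), dtype=bool)
        mv[1:ny, :] = fluid[: ny - 1, :] & fluid[1:, :]
        self.mask_v_unknown = mv
        self.active_v = mv

        self.idx_u = -np.ones((ny, nx + 1), dtype=np.int64)
        self.idx_u[mu] = np.arange(mu.sum())
        self.n_u = int(mu.sum())
        self.idx_v = -np.ones((ny + 1, nx), dtype=np.int64)
        self.idx_v[mv] = np.arange(mv.sum())
        self.n_v = int(mv.sum())
        self.idx_p = -np.ones((ny, nx), dtype=np.int64)
        self.idx_p[fluid] = np.arange(fluid.sum())
        self.n_p = int(fluid.sum())
        self.p_ref = int(self.idx_p[grid.wall_lower_y[0], 0])

        self.inlet_rows = np.arange(grid.wall_lower_y[0], grid.wall_upper_y[0] + 1)
        self.outlet_rows = np.arange(
            grid.wall_lower_y[nx - 1], grid.wall_upper_y[nx - 1] + 1
        )


_STENCILS: dict[int, _Stencil] = {}


def _stencil(grid: Grid2D) -> _Stencil:
    st = _STENCILS.get(id(grid))
    if st is None or st.grid is not grid:
        st = _Stencil(grid)
        if len(_STENCILS) > 8:
            _STENCILS.clear()
        _STENCILS[id(grid)] = st
    return st


def _apply_velocity_bc(u, v, st: _Stencil, inlet: np.ndarray) -> None:
    """Zero solid faces, impose inlet profile and outlet mass correction."""
    grid = st.grid
    nx = grid.nx
    u[~(st.mask_u_unknown | st.mask_u_inlet | st.mask_u_outlet)] = 0.0
    v[~st.mask_v_unknown] = 0.0
    u[:, 0] = 0.0
    u[st.inlet_rows, 0] = inlet
    rows = st.outlet_rows
    u[:, nx] = 0.0
    u_out = u[rows, nx - 1].copy()
    q_in = u[st.inlet_rows, 0].sum() * grid.dy
    q_out = u_out.sum() * grid.dy
    u_out += (q_in - q_out) / (rows.size * grid.dy)
    u[rows, nx] = u_out


def _quick_corr(phi, act, F, P, N, PP, NN):
    """Deferred-correction flux F*(phi_QUICK - phi_upwind) at faces.

    ``phi``/``act`` are pad-by-2 arrays; P/N/PP/NN are slice tuples for the
    upstream node, downstream node, far-upstream and far-downstream of each
    face (positive F flows P -> N).  Falls back to plain upwind (zero
    correction) where either adjacent node is inactive or the needed far
    node is unavailable.
    """
    corr_pos = 0.375 * phi[N] - 0.25 * phi[P] - 0.125 * phi[PP]
    corr_neg = 0.375 * phi[P] - 0.25 * phi[N] - 0.125 * phi[NN]
    corr = np.where(F >= 0, np.where(act[PP], corr_pos, 0.0),
                    np.where(act[NN], corr_neg, 0.0))
    return np.where(act[P] & act[N], F * corr, 0.0)


def _pad2(a):
    return np.pad(a, 2, mode="constant", constant_values=0)


class _System:
    """Workspace for SIMPLE outer iterations on a fixed grid + conditions."""

    def __init__(self, grid, props, settings, bc, body_force, feedback):
        self.grid = grid
        self.props = props
        self.settings = settings
        self.st = _stencil(grid)
        self.inlet = bc.inlet_values(grid)
        self.body_force = body_force
        self.feedback = feedback
        # a stale pressure-correction factorization is safe for weakly
        # varying coefficients, but the strongly coupled feedback system
        # needs the current one every iteration
        if feedback is not None:
            self._pc_refresh = 1
        self.alpha_u = settings.alpha_u
        self.alpha_p = settings.alpha_p
        # deferred-correction damping: the QUICK source is blended with its
        # previous outer-iteration value; the fixed point (and hence the
        # converged field) is the undamped QUICK discretization
        self.dc_blend = 0.5
        self._dc_u = None
        self._dc_v = None
        if body_force is not None and body_force.shape != (grid.ny, grid.nx, 2):
            raise ValueError("body_force must have shape (ny, nx, 2)")

    # -- u momentum ---------------------------------------------------------

    def assemble_u(self, u, v, p, time_coef, time_src):
        grid, st, props, set_ = self.grid, self.st, self.props, self.settings
        ny, nx = grid.ny, grid.nx
        dx, dy, rho, mu_ = grid.dx, grid.dy, props.rho, props.mu
        vol = dx * dy

        # work arrays indexed [i, j-1] for u CVs at columns j = 1..nx-1
        Fe = rho * dy * 0.5 * (u[:, 1:nx] + u[:, 2 : nx + 1])
        Fw = rho * dy * 0.5 * (u[:, 0 : nx - 1] + u[:, 1:nx])
        Fn = rho * dx * 0.5 * (v[1:, 0 : nx - 1] + v[1:, 1:nx])
        Fs = rho * dx * 0.5 * (v[:ny, 0 : nx - 1] + v[:ny, 1:nx])

        mu_pad = np.pad(st.mask_u_unknown, ((1, 1), (0, 0)))
        nbN = mu_pad[2:, 1:nx]  # u[i+1, j] is an unknown
        nbS = mu_pad[:-2, 1:nx]
        De = Dw = mu_ * dy / dx
        Dn = np.where(nbN, mu_ * dx / dy, 2.0 * mu_ * dx / dy)
        Ds = np.where(nbS, mu_ * dx / dy, 2.0 * mu_ * dx / dy)

        aE = De + np.maximum(-Fe, 0.0)
        aW = Dw + np.maximum(Fw, 0.0)
        aN = Dn + np.maximum(-Fn, 0.0)
        aS = Ds + np.maximum(Fs, 0.0)
        aP = aE + aW + aN + aS + (Fe - Fw + Fn - Fs) + time_coef * vol

        b = (p[:, 0 : nx - 1] - p[:, 1:nx]) * dy + time_src[:, 1:nx] * vol

        if self.body_force is not None:
            fx = self.body_force[:, :, 0]
            b = b + 0.5 * (fx[:, 0 : nx - 1] + fx[:, 1:nx]) * vol
        fb = self.feedback
        if fb is not None:
            ex, ey = fb.beam
            gf = 0.5 * (fb.gain[:, 0 : nx - 1] + fb.gain[:, 1:nx])
            vmf = 0.5 * (fb.vm[:, 0 : nx - 1] + fb.vm[:, 1:nx])
            v4 = 0.25 * (v[:ny, 0 : nx - 1] + v[:ny, 1:nx] + v[1:, 0 : nx - 1] + v[1:, 1:nx])
            aP = aP + gf * ex * ex * vol
            b = b + gf * ex * (vmf - ey * v4) * vol

        if set_.convection_scheme == "quick":
            up = _pad2(u)
            au = _pad2(st.active_u)
            # padded coords: u[i, j] -> up[i+2, j+2]; centers j = 1..nx-1
            R = np.s_[2 : ny + 2]
            cP = np.s_[3 : nx + 2]
            fe = _quick_corr(up, au, Fe,
                             (R, cP), (R, np.s_[4 : nx + 3]),
                             (R, np.s_[2 : nx + 1]), (R, np.s_[5 : nx + 4]))
            fw = _quick_corr(up, au, Fw,
                             (R, np.s_[2 : nx + 1]), (R, cP),
                             (R, np.s_[1:nx]), (R, np.s_[4 : nx + 3]))
            fn = _quick_corr(up, au, Fn,
                             (np.s_[2 : ny + 2], cP), (np.s_[3 : ny + 3], cP),
                             (np.s_[1 : ny + 1], cP), (np.s_[4 : ny + 4], cP))
            fs = _quick_corr(up, au, Fs,
                             (np.s_[1 : ny + 1], cP), (np.s_[2 : ny + 2], cP),
                             (np.s_[0:ny], cP), (np.s_[3 : ny + 3], cP))
            corr = fe - fw + fn - fs
            if self._dc_u is not None:
                corr = self.dc_blend * corr + (1.0 - self.dc_blend) * self._dc_u
            self._dc_u = corr
            b = b - corr

        mu_c = st.mask_u_unknown[:, 1:nx]
        nbE = st.mask_u_unknown[:, 2 : nx + 1]
        nbW = st.mask_u_unknown[:, 0 : nx - 1]
        # known east/west neighbor values (inlet, outlet, or wall zeros)
        b_full = b + aE * np.where(~nbE, u[:, 2 : nx + 1], 0.0) \
                   + aW * np.where(~nbW, u[:, 0 : nx - 1], 0.0)

        u_pad = np.pad(u, ((1, 1), (0, 0)))
        res2d = (
            aP * u[:, 1:nx]
            - aE * np.where(nbE, u[:, 2 : nx + 1], 0.0)
            - aW * np.where(nbW, u[:, 0 : nx - 1], 0.0)
            - aN * np.where(nbN, u_pad[2:, 1:nx], 0.0)
            - aS * np.where(nbS, u_pad[:-2, 1:nx], 0.0)
            - b_full
        )
        res = float(np.abs(res2d[mu_c]).sum())
        scale = max(
            float(np.abs(aP[mu_c] * u[:, 1:nx][mu_c]).sum()),
            float(np.abs(b_full[mu_c]).sum()),
        )

        alpha = self.alpha_u
        aP_rel = aP / alpha
        b_rel = b_full + (1.0 - alpha) / alpha * aP * u[:, 1:nx]

        idx = st.idx_u[:, 1:nx]
        ip = np.pad(st.idx_u, ((1, 1), (0, 0)), constant_values=-1)
        rows = [idx[mu_c]]
        cols = [idx[mu_c]]
        data = [aP_rel[mu_c]]
        for a_nb, nb_mask, nb_idx in (
            (aE, nbE, st.idx_u[:, 2 : nx + 1]),
            (aW, nbW, st.idx_u[:, 0 : nx - 1]),
            (aN, nbN, ip[2:, 1:nx]),
            (aS, nbS, ip[:-2, 1:nx]),
        ):
            sel = mu_c & nb_mask
            rows.append(idx[sel])
            cols.append(nb_idx[sel])
            data.append(-a_nb[sel])
        A = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(st.n_u, st.n_u),
        )
        aP_grid = np.zeros((ny, nx + 1))
        aP_grid[:, 1:nx] = aP_rel
        return A, b_rel[mu_c], (res, scale), aP_grid

    # -- v momentum ---------------------------------------------------------

    def assemble_v(self, u, v, p, time_coef, time_src):
        grid, st, props, set_ = self.grid, self.st, self.props, self.settings
        ny, nx = grid.ny, grid.nx
        dx, dy, rho, mu_ = grid.dx, grid.dy, props.rho, props.mu
        vol = dx * dy

        # work arrays indexed [i-1, j] for v CVs at rows i = 1..ny-1
        Fe = rho * dy * 0.5 * (u[: ny - 1, 1:] + u[1:, 1:])
        Fw = rho * dy * 0.5 * (u[: ny - 1, :nx] + u[1:, :nx])
        Fn = rho * dx * 0.5 * (v[1:ny, :] + v[2:, :])
        Fs = rho * dx * 0.5 * (v[0 : ny - 1, :] + v[1:ny, :])

        mv_pad = np.pad(st.mask_v_unknown, ((0, 0), (1, 1)))
        nbE = mv_pad[1:ny, 2:]
        nbW = mv_pad[1:ny, :-2]
        Dn = Ds = mu_ * dx / dy
        # east/west walls and the inlet plane sit half a cell away;
        # the outlet column east neighbor is the lagged zero-gradient value
        De = np.where(nbE, mu_ * dy / dx, 2.0 * mu_ * dy / dx)
        Dw = np.where(nbW, mu_ * dy / dx, 2.0 * mu_ * dy / dx)
        De[:, nx - 1] = mu_ * dy / dx

        aE = De + np.maximum(-Fe, 0.0)
        aW = Dw + np.maximum(Fw, 0.0)
        aN = Dn + np.maximum(-Fn, 0.0)
        aS = Ds + np.maximum(Fs, 0.0)
        aP = aE + aW + aN + aS + (Fe - Fw + Fn - Fs) + time_coef * vol

        b = (p[0 : ny - 1, :] - p[1:ny, :]) * dx + time_src[1:ny, :] * vol

        if self.body_force is not None:
            fy = self.body_force[:, :, 1]
            b = b + 0.5 * (fy[0 : ny - 1, :] + fy[1:ny, :]) * vol
        fb = self.feedback
        if fb is not None:
            ex, ey = fb.beam
            gf = 0.5 * (fb.gain[0 : ny - 1, :] + fb.gain[1:ny, :])
            vmf = 0.5 * (fb.vm[0 : ny - 1, :] + fb.vm[1:ny, :])
            u4 = 0.25 * (u[: ny - 1, :nx] + u[: ny - 1, 1:] + u[1:, :nx] + u[1:, 1:])
            aP = aP + gf * ey * ey * vol
            b = b + gf * ey * (vmf - ex * u4) * vol

        if set_.convection_scheme == "quick":
            vp = _pad2(v)
            av = _pad2(st.active_v)
            # padded coords: v[i, j] -> vp[i+2, j+2]; centers i = 1..ny-1
            Rp = np.s_[3 : ny + 2]
            C = np.s_[2 : nx + 2]
            fe = _quick_corr(vp, av, Fe,
                             (Rp, C), (Rp, np.s_[3 : nx + 3]),
                             (Rp, np.s_[1 : nx + 1]), (Rp, np.s_[4 : nx + 4]))
            fw = _quick_corr(vp, av, Fw,
                             (Rp, np.s_[1 : nx + 1]), (Rp, C),
                             (Rp, np.s_[0:nx]), (Rp, np.s_[3 : nx + 3]))
            fn = _quick_corr(vp, av, Fn,
                             (Rp, C), (np.s_[4 : ny + 3], C),
                             (np.s_[2 : ny + 1], C), (np.s_[5 : ny + 4], C))
            fs = _quick_corr(vp, av, Fs,
                             (np.s_[2 : ny + 1], C), (Rp, C),
                             (np.s_[1 : ny], C), (np.s_[4 : ny + 3], C))
            corr = fe - fw + fn - fs
            if self._dc_v is not None:
                corr = self.dc_blend * corr + (1.0 - self.dc_blend) * self._dc_v
            self._dc_v = corr
            b = b - corr

        mv_c = st.mask_v_unknown[1:ny, :]
        nbN_ = st.mask_v_unknown[2 : ny + 1, :]
        nbS_ = st.mask_v_unknown[0 : ny - 1, :]
        # known east value: lagged zero-gradient at the outlet column
        vE_known = np.zeros_like(b)
        vE_known[:, nx - 1] = v[1:ny, nx - 1]
        b_full = b + aE * np.where(~nbE, vE_known, 0.0)  # west knowns are 0

        v_padE = np.pad(v, ((0, 0), (0, 1)))
        v_padW = np.pad(v, ((0, 0), (1, 0)))
        res2d = (
            aP * v[1:ny, :]
            - aE * np.where(nbE, v_padE[1:ny, 1:], 0.0)
            - aW * np.where(nbW, v_padW[1:ny, :nx], 0.0)
            - aN * np.where(nbN_, v[2 : ny + 1, :], 0.0)
            - aS * np.where(nbS_, v[0 : ny - 1, :], 0.0)
            - b_full
        )
        res = float(np.abs(res2d[mv_c]).sum())
        scale = max(
            float(np.abs(aP[mv_c] * v[1:ny, :][mv_c]).sum()),
            float(np.abs(b_full[mv_c]).sum()),
        )

        alpha = self.alpha_u
        aP_rel = aP / alpha
        b_rel = b_full + (1.0 - alpha) / alpha * aP * v[1:ny, :]

        idx = st.idx_v[1:ny, :]
        ipad = np.pad(st.idx_v, ((0, 1), (1, 1)), constant_values=-1)
        rows = [idx[mv_c]]
        cols = [idx[mv_c]]
        data = [aP_rel[mv_c]]
        for a_nb, nb_mask, nb_idx in (
            (aE, nbE, ipad[1:ny, 2:]),
            (aW, nbW, ipad[1:ny, :-2]),
            (aN, nbN_, st.idx_v[2 : ny + 1, :]),
            (aS, nbS_, st.idx_v[0 : ny - 1, :]),
        ):
            sel = mv_c & nb_mask
            rows.append(idx[sel])
            cols.append(nb_idx[sel])
            data.append(-a_nb[sel])
        A = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(st.n_v, st.n_v),
        )
        aP_grid = np.zeros((ny + 1, nx))
        aP_grid[1:ny, :] = aP_rel
        return A, b_rel[mv_c], (res, scale), aP_grid

    # -- pressure correction -------------------------------------------------

    _pc_lu = None
    _pc_age = 0
    _pc_refresh = 25

    def pressure_correction(self, u, v, aPu, aPv):
        grid, st = self.grid, self.st
        ny, nx = grid.ny, grid.nx
        dx, dy, rho = grid.dx, grid.dy, self.props.rho

        du = np.where(st.mask_u_unknown, dy / np.where(aPu > 0, aPu, 1.0), 0.0)
        dv = np.where(st.mask_v_unknown, dx / np.where(aPv > 0, aPv, 1.0), 0.0)

        aE = rho * dy * du[:, 1:]
        aW = rho * dy * du[:, :nx]
        aN = rho * dx * dv[1:, :]
        aS = rho * dx * dv[:ny, :]
        b = rho * ((u[:, :nx] - u[:, 1:]) * dy + (v[:ny, :] - v[1:, :]) * dx)
        m = grid.fluid
        rhs = b[m].copy()
        rhs[st.p_ref] = 0.0
        # The correction matrix varies only weakly between outer iterations
        # (through the momentum diagonal); a frozen factorization changes the
        # convergence path, not the converged field, since rhs -> 0.
        if self._pc_lu is None or self._pc_age >= self._pc_refresh:
            aP = aE + aW + aN + aS
            idx = st.idx_p
            ipad = np.pad(idx, 1, constant_values=-1)
            rows = [idx[m]]
            cols = [idx[m]]
            data = [np.where(aP[m] > 0, aP[m], 1.0)]
            for a_nb, nb_idx in (
                (aE, ipad[1:-1, 2:]),
                (aW, ipad[1:-1, :-2]),
                (aN, ipad[2:, 1:-1]),
                (aS, ipad[:-2, 1:-1]),
            ):
                sel = m & (a_nb > 0)
                rows.append(idx[sel])
                cols.append(nb_idx[sel])
                data.append(-a_nb[sel])
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            data = np.concatenate(data)
            keep = rows != st.p_ref
            rows = np.append(rows[keep], st.p_ref)
            cols = np.append(cols[keep], st.p_ref)
            data = np.append(data[keep], 1.0)
            A = sp.csc_matrix((data, (rows, cols)), shape=(st.n_p, st.n_p))
            self._pc_lu = spla.splu(A)
            self._pc_age = 0
        self._pc_age += 1
        pc = np.zeros((ny, nx))
        pc[m] = self._pc_lu.solve(rhs)
        return pc, du, dv

    def mass_residual(self, u, v):
        grid = self.grid
        b = self.props.rho * (
            (u[:, : grid.nx] - u[:, 1:]) * grid.dy
            + (v[: grid.ny, :] - v[1:, :]) * grid.dx
        )
        imb = float(np.abs(b[grid.fluid]).sum())
        q_in = float(np.abs(self.inlet).sum() * grid.dy) * self.props.rho
        u_scale = float(np.abs(u).mean()) * grid.dy * grid.ny * self.props.rho
        return imb / max(q_in, u_scale, 1e-12)


def _iterate(sys_, field, time_coef, time_src_u, time_src_v, tol, max_iters):
    st = sys_.st
    grid = sys_.grid
    settings = sys_.settings
    u = field.u.copy()
    v = field.v.copy()
    p = field.p.copy()
    _apply_velocity_bc(u, v, st, sys_.inlet)

    history: list[tuple[float, float, float]] = []
    for it in range(max_iters):
        # momentum solves are sequenced (v assembled after the u update) to
        # reduce the lag of the cross-coupled feedback terms
        rm = sys_.mass_residual(u, v)
        Au, bu, (res_u, sc_u), aPu = sys_.assemble_u(u, v, p, time_coef, time_src_u)
        if st.n_u:
            u[st.mask_u_unknown] = spla.spsolve(Au, bu)
        _apply_velocity_bc(u, v, st, sys_.inlet)
        Av, bv, (res_v, sc_v), aPv = sys_.assemble_v(u, v, p, time_coef, time_src_v)
        # both momentum residuals are non-dimensionalised by the dominant
        # momentum scale; the transverse equation would otherwise gate
        # convergence on a near-zero self-scale in channel-like flows
        scale = max(sc_u, sc_v, 1e-14)
        ru = res_u / scale
        rv = res_v / scale
        history.append((ru, rv, rm))
        if not (np.isfinite(ru) and np.isfinite(rv) and np.isfinite(rm)):
            raise ConvergenceError(f"non-finite residual at outer iteration {it}", history)
        if ru < tol and rv < tol and rm < tol:
            return FlowField(u, v, p, field.t), history
        if st.n_v:
            v[st.mask_v_unknown] = spla.spsolve(Av, bv)
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise ConvergenceError(f"non-finite velocity at outer iteration {it}", history)
        _apply_velocity_bc(u, v, st, sys_.inlet)

        pc, du, dv = sys_.pressure_correction(u, v, aPu, aPv)
        pc_pad = np.pad(pc, 1)
        u += du * (pc_pad[1:-1, : grid.nx + 1] - pc_pad[1:-1, 1:])
        v += dv * (pc_pad[: grid.ny + 1, 1:-1] - pc_pad[1:, 1:-1])
        p += sys_.alpha_p * pc
        _apply_velocity_bc(u, v, st, sys_.inlet)

        # oscillatory stagnation (strong feedback coupling): damp harder
        if (it + 1) % 80 == 0 and sys_.alpha_u > 0.15:
            sys_.alpha_u *= 0.6
            sys_.alpha_p *= 0.6
            sys_.dc_blend *= 0.6
            sys_._pc_lu = None

    raise ConvergenceError(
        f"no convergence in {max_iters} outer iterations "
        f"(last residuals u={history[-1][0]:.3g} v={history[-1][1]:.3g} "
        f"m={history[-1][2]:.3g})",
        history,
    )


# ---------------------------------------------------------------------------
# public operations


def step(
    field: FlowField,
    bc: BoundaryCondition,
    props: FluidProps,
    settings: SolverSettings,
    grid: Grid2D,
    body_force: Optional[np.ndarray] = None,
    field_prev: Optional[FlowField] = None,
    feedback: Optional[FeedbackTerm] = None,
) -> FlowField:
    """Advance one time step of size ``settings.dt``.

    Uses BDF2 when ``field_prev`` (the state one step before ``field``) is
    supplied, backward Euler otherwise.  ``body_force`` is an explicit
    cell-centered force density (ny, nx, 2) in N/m^3; ``feedback`` an
    implicit Doppler-forcing term.  Raises :class:`ConvergenceError` with
    the residual history on non-convergence or non-finite values.
    """
    sys_ = _System(grid, props, settings, bc, body_force, feedback)
    rho, dt = props.rho, settings.dt
    if field_prev is None:
        coef = rho / dt
        src_u = rho / dt * field.u
        src_v = rho / dt * field.v
    else:
        coef = 1.5 * rho / dt
        src_u = rho / dt * (2.0 * field.u - 0.5 * field_prev.u)
        src_v = rho / dt * (2.0 * field.v - 0.5 * field_prev.v)
    out, _ = _iterate(
        sys_, field, coef, src_u, src_v, settings.residual_tol, settings.max_outer_iters
    )
    out.t = field.t + dt
    return out


def solve_steady(
    grid: Grid2D,
    bc: BoundaryCondition,
    props: FluidProps,
    settings: Optional[SolverSettings] = None,
    initial: Optional[FlowField] = None,
    feedback: Optional[FeedbackTerm] = None,
    body_force: Optional[np.ndarray] = None,
    tol: float = 1.0e-5,
    max_iters: int = 4000,
) -> FlowField:
    """Iterate the coupled system without a time term to a steady state."""
    settings = settings or SolverSettings()
    sys_ = _System(grid, props, settings, bc, body_force, feedback)
    sys_._pc_refresh = 1  # the state moves far during a steady solve
    field = initial.copy() if initial is not None else FlowField.zeros(grid)
    out, _ = _iterate(
        sys_, field, 0.0, np.zeros_like(field.u), np.zeros_like(field.v), tol, max_iters
    )
    return out


def compute_wss(
    field: FlowField, props: FluidProps, grid: Grid2D, wall: str = "lower"
) -> np.ndarray:
    """Wall shear stress per column, one-sided at the stair-step wall.

    ``wall="lower"`` is the deeper wall (larger y, ultrasound display
    convention; rows ``grid.wall_upper_y``), ``wall="upper"`` the shallower
    one.  tau = mu du/dn with n pointing from the wall into the fluid, so
    tau > 0 for downstream flow at either wall.  Uses the half-cell
    one-sided gradient tau = 2 mu u_1 / dy, consistent with the solver's
    wall flux (exact for discrete fully-developed Poiseuille flow).
    """
    if wall not in ("lower", "upper"):
        raise ValueError("wall must be 'lower' or 'upper'")
    rows = grid.wall_upper_y if wall == "lower" else grid.wall_lower_y
    cols = np.arange(grid.nx)
    u_c = 0.5 * (field.u[rows, cols] + field.u[rows, cols + 1])
    return 2.0 * props.mu * u_c / grid.dy


def space_average_wss(series: np.ndarray, x_range: tuple[int, int]) -> float:
    """Arithmetic mean of a per-column WSS series over columns
    ``x_range = (j0, j1)`` (half-open, 0-based)."""
    j0, j1 = x_range
    if j1 <= j0 or j0 < 0 or j1 > len(series):
        raise ValueError("empty or out-of-range x_range")
    return float(np.mean(series[j0:j1]))
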