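"""Axisymmetric incompressible Navier–Stokes solver on a body-fitted tube.

The incompressible Navier–Stokes equations (Newtonian blood, rigid walls)

    rho (du/dt + u . grad u) = -grad p + mu lap u,     div u = 0

are solved in cylindrical coordinates (z, r) without swirl on the mapped
rectangle xi = z, eta = r / R(z), with R(z) the wall-radius law of the
fistula path.  Variables are staggered MAC-style: axial velocity u on
xi-faces, radial velocity v on eta-faces, pressure on cells.

Time discretization is backward Euler with Picard (outer) iterations:
each iteration solves an implicit-diffusion momentum predictor with
second-order upwind convection evaluated at the previous iterate, then an
incremental pressure-correction projection.  The projection operator is
the exact composition of the discrete divergence (conservative
contravariant fluxes of the mapped metric) with the through-face pressure
gradient, so cell divergence vanishes to direct-solver precision after
every step.  The time step adapts on a halving ladder to keep the
advective CFL number at or below the prescribed cap (0.1 by default).

Boundary conditions: prescribed inlet velocity profile (parabolic by
default), zero-pressure outlet with zero-gradient outflow velocity,
no-slip wall at eta = 1, symmetry at the axis eta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ..flowbc import BLOOD, FluidProperties, InletCondition
from ..synth import ValidationError
from .grids import TubeGrid

__all__ = ["FlowField", "AxisymmetricSolver", "solve_unsteady", "solve_steady"]


class SolverError(RuntimeError):
    """Numerical failure (non-convergence); carries the residual trace."""

    def __init__(self, msg, residual_trace=None):
        super().__init__(msg)
        self.residual_trace = residual_trace


@dataclass
class FlowField:
    """Stored phase snapshots of the final cycle plus solver diagnostics."""

    grid: TubeGrid
    phase_times: np.ndarray  # times (s) of stored snapshots, final cycle
    u: list  # (nz+1, nr) per snapshot
    v: list  # (nz, nr+1)
    p: list  # (nz, nr), Pa, relative to the outlet
    inlet_flow: np.ndarray  # m^3/s per snapshot
    inlet_pressure_trace: np.ndarray  # (n_cycles, n_phase) Pa
    phase_grid: np.ndarray  # phase fractions of the trace
    cfl_history: np.ndarray
    residual_history: np.ndarray
    max_divergence: float
    n_cycles: int
    period_s: float

    @property
    def n_phases(self) -> int:
        return len(self.u)

    def peak_systole_index(self) -> int:
        return int(np.argmax(self.inlet_flow))

    def cell_velocity(self, k: int):
        """Interpolate (u, v) of snapshot ``k`` to cell centers."""
        u, v = self.u[k], self.v[k]
        uc = 0.5 * (u[:-1, :] + u[1:, :])
        vc = 0.5 * (v[:, :-1] + v[:, 1:])
        return uc, vc

    def speed(self, k: int):
        uc, vc = self.cell_velocity(k)
        return np.hypot(uc, vc)


def _reflect_eta_u(j, nr):
    """Map an eta index of the u array onto a DOF index + sign, using axis
    (even) and wall (odd) reflection."""
    jj = np.asarray(j)
    sign = np.ones_like(jj, dtype=float)
    neg = jj < 0
    jj = np.where(neg, -1 - jj, jj)
    over = jj > nr - 1
    jj = np.where(over, 2 * nr - 1 - jj, jj)
    sign = np.where(over, -sign, sign)
    return jj, sign


class AxisymmetricSolver:
    """Operator cache + time stepper for one grid/fluid pairing."""

    def __init__(self, grid: TubeGrid, fluid: FluidProperties = BLOOD):
        self.grid = grid
        self.fluid = fluid
        self.nu = fluid.kinematic_viscosity
        nz, nr = grid.nz, grid.nr
        self.nu_dof = (nz + 1) * nr
        self.nv_dof = nz * (nr + 1)
        self.np_dof = nz * nr
        self._build_projection_ops()
        self._build_laplacians()
        self._mom_cache: dict[tuple[float, str], object] = {}

    # -- index helpers ---------------------------------------------------

    def _iu(self, i, j):
        return i * self.grid.nr + j

    def _iv(self, i, j):
        return i * (self.grid.nr + 1) + j

    def _ip(self, i, j):
        return i * self.grid.nr + j

    # -- projection operators -------------------------------------------

    def _build_projection_ops(self):
        g = self.grid
        nz, nr = g.nz, g.nr
        dxi, deta = g.dxi, g.deta
        etac = g.eta_cell
        etaf = g.eta_face
        vol = g.cell_volumes()  # (nz, nr)

        rows, cols, vals = [], [], []
        # axial fluxes: cell (i,j) gains u[i+1,j]*c(i+1,j) - u[i,j]*c(i,j)
        I, J = np.meshgrid(np.arange(nz), np.arange(nr), indexing="ij")
        cell = self._ip(I, J).ravel()
        for face_i, sgn in ((I + 1, 1.0), (I, -1.0)):
            c = etac[J] * g.R_face[face_i] ** 2 * deta / vol[I, J]
            rows.append(cell)
            cols.append(self._iu(face_i, J).ravel())
            vals.append((sgn * c).ravel())
        # radial fluxes via the u-interpolation part of the contravariant V
        # F_r(i, jf) = (v - eta_jf Rp_c u_bar) eta_jf R_c dxi, jf = 1..nr-1
        for jf_off, sgn in ((1, 1.0), (0, -1.0)):  # faces j+1 and j
            JF = J + jf_off
            interior = (JF >= 1) & (JF <= nr - 1)
            coef = np.where(
                interior, etaf[JF] * g.R_cell[I] * dxi / vol[I, J], 0.0
            ) * sgn
            geom = -etaf[JF] * g.Rp_cell[I] * 0.25
            for di in (0, 1):
                for dj in (-1, 0):
                    jj = np.clip(JF + dj, 0, nr - 1)
                    rows.append(cell)
                    cols.append(self._iu(I + di, jj).ravel())
                    vals.append((coef * geom).ravel())
        Du = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.np_dof, self.nu_dof),
        )

        rows, cols, vals = [], [], []
        for jf_off, sgn in ((1, 1.0), (0, -1.0)):
            JF = J + jf_off
            interior = (JF >= 1) & (JF <= nr - 1)
            coef = np.where(interior, etaf[JF] * g.R_cell[I] * dxi / vol[I, J], 0.0)
            rows.append(cell)
            cols.append(self._iv(I, JF).ravel())
            vals.append((sgn * coef).ravel())
        Dv = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.np_dof, self.nv_dof),
        )

        # through-face pressure gradients used by the correction step
        rows, cols, vals = [], [], []
        Iu, Ju = np.meshgrid(np.arange(1, nz), np.arange(nr), indexing="ij")
        r = self._iu(Iu, Ju).ravel()
        rows += [r, r]
        cols += [self._ip(Iu, Ju).ravel(), self._ip(Iu - 1, Ju).ravel()]
        vals += [np.full(r.size, 1.0 / dxi), np.full(r.size, -1.0 / dxi)]
        jout = np.arange(nr)
        r = self._iu(np.full(nr, nz), jout)
        rows.append(r)
        cols.append(self._ip(np.full(nr, nz - 1), jout))
        vals.append(np.full(nr, -2.0 / dxi))  # ghost = -p: zero face pressure
        Gu = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nu_dof, self.np_dof),
        )

        rows, cols, vals = [], [], []
        Iv, Jv = np.meshgrid(np.arange(nz), np.arange(1, nr), indexing="ij")
        r = self._iv(Iv, Jv).ravel()
        coef = (1.0 / (g.R_cell[Iv] * deta)).ravel()
        rows += [r, r]
        cols += [self._ip(Iv, Jv).ravel(), self._ip(Iv, Jv - 1).ravel()]
        vals += [coef, -coef]
        Gv = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nv_dof, self.np_dof),
        )

        self.Du, self.Dv, self.Gu, self.Gv = Du, Dv, Gu, Gv
        A = (Du @ Gu + Dv @ Gv).tocsc()
        self._proj_lu = splu(A)

    # -- momentum Laplacians ---------------------------------------------

    def _laplacian_u(self):
        """Mapped axisymmetric Laplacian acting on u DOFs (interior rows)."""
        g = self.grid
        nz, nr = g.nz, g.nr
        dxi, deta = g.dxi, g.deta
        I, J = np.meshgrid(np.arange(1, nz), np.arange(nr), indexing="ij")
        rows_idx = self._iu(I, J).ravel()
        etac = g.eta_cell[J]
        R = g.R_face[I]
        Rp = g.Rp_face[I]
        Rpp = g.Rpp_face[I]
        a = etac * Rp / R
        b = etac * (Rpp * R - 2 * Rp**2) / R**2
        c_xx = 1.0 / dxi**2
        c_ee = (a**2 + 1.0 / R**2) / deta**2
        c_e = (1.0 / (R**2 * etac) - b) / (2 * deta)
        c_xe = -2.0 * a / (4 * dxi * deta)

        rows, cols, vals = [], [], []

        def add(di, dj, coef):
            """Accumulate a stencil entry, folding eta ghosts.

            Axis ghost (even): u[-1] = u[0].  Wall ghost (quadratic
            through the no-slip wall): u[nr] = -2 u[nr-1] + u[nr-2]/3,
            which keeps parabolic profiles exact discrete solutions and
            the wall shear second-order accurate.
            """
            jj = J + dj
            over = jj > nr - 1  # wall ghost (only jj = nr can occur)
            under = jj < 0  # axis ghost (only jj = -1)
            jj_in = np.where(under, 0, np.where(over, nr - 1, jj))
            rows.append(rows_idx)
            cols.append(self._iu(I + di, jj_in).ravel())
            vals.append((coef * np.where(over, -2.0, 1.0)).ravel())
            if np.any(over):
                rows.append(rows_idx[over.ravel()])
                cols.append(self._iu(I + di, np.full_like(jj_in, nr - 2))[over].ravel())
                vals.append((coef * np.ones_like(jj_in) / 3.0)[over].ravel())
        add(0, 0, -2 * c_xx - 2 * c_ee)
        add(1, 0, np.full_like(a, c_xx))
        add(-1, 0, np.full_like(a, c_xx))
        add(0, 1, c_ee + c_e)
        add(0, -1, c_ee - c_e)
        add(1, 1, c_xe)
        add(-1, -1, c_xe)
        add(1, -1, -c_xe)
        add(-1, 1, -c_xe)
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nu_dof, self.nu_dof),
        )

    def _laplacian_v(self):
        """Mapped Laplacian minus 1/r^2 acting on v DOFs (interior rows).

        xi ghosts: odd reflection at the inlet (v = 0 on the inlet plane),
        even (zero-gradient) at the outlet.
        """
        g = self.grid
        nz, nr = g.nz, g.nr
        dxi, deta = g.dxi, g.deta
        I, J = np.meshgrid(np.arange(nz), np.arange(1, nr), indexing="ij")
        rows_idx = self._iv(I, J).ravel()
        eta = g.eta_face[J]
        R = g.R_cell[I]
        Rp = g.Rp_cell[I]
        Rpp = g.Rpp_cell[I]
        a = eta * Rp / R
        b = eta * (Rpp * R - 2 * Rp**2) / R**2
        c_xx = 1.0 / dxi**2
        c_ee = (a**2 + 1.0 / R**2) / deta**2
        c_e = (1.0 / (R**2 * eta) - b) / (2 * deta)
        c_xe = -2.0 * a / (4 * dxi * deta)
        c_0 = -1.0 / (eta * R) ** 2  # the -v/r^2 term

        rows, cols, vals = [], [], []

        def add(di, dj, coef):
            ii = I + di
            sgn = np.ones_like(coef)
            under = ii < 0
            over = ii > nz - 1
            ii = np.where(under, -1 - ii, ii)
            sgn = np.where(under, -sgn, sgn)  # odd at inlet
            ii = np.where(over, 2 * nz - 1 - ii, ii)  # even at outlet
            rows.append(rows_idx)
            cols.append(self._iv(ii, J + dj).ravel())
            vals.append((coef * sgn).ravel())

        add(0, 0, -2 * c_xx - 2 * c_ee + c_0)
        add(1, 0, np.full_like(a, c_xx))
        add(-1, 0, np.full_like(a, c_xx))
        add(0, 1, c_ee + c_e)
        add(0, -1, c_ee - c_e)
        add(1, 1, c_xe)
        add(-1, -1, c_xe)
        add(1, -1, -c_xe)
        add(-1, 1, -c_xe)
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nv_dof, self.nv_dof),
        )

    def _build_laplacians(self):
        g = self.grid
        nz, nr = g.nz, g.nr
        self.Lu = self._laplacian_u()
        self.Lv = self._laplacian_v()
        # interior-row selectors
        mu = np.zeros(self.nu_dof)
        mu[self._iu(*np.meshgrid(np.arange(1, nz), np.arange(nr), indexing="ij")).ravel()] = 1.0
        self.mask_u = mu
        mv = np.zeros(self.nv_dof)
        mv[self._iv(*np.meshgrid(np.arange(nz), np.arange(1, nr), indexing="ij")).ravel()] = 1.0
        self.mask_v = mv
        # boundary relation rows
        rows, cols, vals = [], [], []
        j = np.arange(nr)
        inlet = self._iu(np.zeros(nr, int), j)
        rows.append(inlet); cols.append(inlet); vals.append(np.ones(nr))
        outlet = self._iu(np.full(nr, nz), j)
        rows += [outlet, outlet]
        cols += [outlet, self._iu(np.full(nr, nz - 1), j)]
        vals += [np.ones(nr), -np.ones(nr)]
        self.Bu = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nu_dof, self.nu_dof),
        )
        rows, cols, vals = [], [], []
        i = np.arange(nz)
        for jf in (0, nr):
            r = self._iv(i, np.full(nz, jf))
            rows.append(r); cols.append(r); vals.append(np.ones(nz))
        self.Bv = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nv_dof, self.nv_dof),
        )

    def _momentum_lu(self, dt: float, which: str):
        key = (dt, which)
        if key not in self._mom_cache:
            if which == "u":
                M = sp.diags(self.mask_u / dt) - self.nu * sp.diags(self.mask_u) @ self.Lu + self.Bu
            else:
                M = sp.diags(self.mask_v / dt) - self.nu * sp.diags(self.mask_v) @ self.Lv + self.Bv
            self._mom_cache[key] = splu(M.tocsc())
            if len(self._mom_cache) > 24:
                self._mom_cache.pop(next(iter(self._mom_cache)))
        return self._mom_cache[key]

    # -- explicit terms ---------------------------------------------------

    def _convection(self, u, v):
        """Second-order upwind convective terms for u and v (interior)."""
        g = self.grid
        nz, nr = g.nz, g.nr
        dxi, deta = g.dxi, g.deta
        etac, etaf = g.eta_cell, g.eta_face

        # ---- u equation: adv_xi = u, adv_eta = (v_bar - eta Rp u)/R
        vbar = 0.25 * (
            v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:]
        )  # at interior u-faces i=1..nz-1
        u_int = u[1:-1, :]
        a_geom = etac[None, :] * g.Rp_face[1:-1, None]
        adv_eta_u = (vbar - a_geom * u_int) / g.R_face[1:-1, None]

        # eta-ghost-padded u (axis even, wall odd), full xi range
        up = np.concatenate(
            [u[:, 1:2], u[:, 0:1], u, -u[:, -1:], -u[:, -2:-1]], axis=1
        )  # columns: j=-2,-1,0..nr-1,nr,nr+1 -> index j+2
        J = np.arange(nr) + 2
        u_c = up[1:-1, :]

        def d_eta(phi_pad, rows):  # rows: slice in xi of the padded array
            c = phi_pad[rows, :]
            fwd2 = (-3 * c[:, J] + 4 * c[:, J + 1] - c[:, J + 2]) / (2 * deta)
            bwd2 = (3 * c[:, J] - 4 * c[:, J - 1] + c[:, J - 2]) / (2 * deta)
            return fwd2, bwd2

        fwd2, bwd2 = d_eta(up, slice(1, nz))
        conv_u = adv_eta_u * np.where(adv_eta_u >= 0, bwd2, fwd2)

        # xi derivative at interior faces (2nd order upwind, 1st near ends)
        uc = u[1:-1, :]
        adv_xi = uc
        bwd1 = (uc - u[:-2, :]) / dxi
        fwd1 = (u[2:, :] - uc) / dxi
        bwd2x = np.full_like(uc, np.nan)
        fwd2x = np.full_like(uc, np.nan)
        bwd2x[1:, :] = (3 * u[2:-1, :] - 4 * u[1:-2, :] + u[:-3, :]) / (2 * dxi)
        fwd2x[:-1, :] = (-3 * u[1:-2, :] + 4 * u[2:-1, :] - u[3:, :]) / (2 * dxi)
        dudxi = np.where(
            adv_xi >= 0,
            np.where(np.isnan(bwd2x), bwd1, bwd2x),
            np.where(np.isnan(fwd2x), fwd1, fwd2x),
        )
        conv_u = conv_u + adv_xi * dudxi

        # ---- v equation (interior eta faces j=1..nr-1, all i)
        ubar = 0.25 * (
            u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:]
        )  # at v-faces j=1..nr-1
        v_int = v[:, 1:-1]
        adv_eta_v = (
            v_int - etaf[None, 1:-1] * g.Rp_cell[:, None] * ubar
        ) / g.R_cell[:, None]

        # eta-padded v: below axis odd (v[-1] = -v[1]), above wall odd
        vp = np.concatenate(
            [-v[:, 2:3], -v[:, 1:2], v, -v[:, -2:-1], -v[:, -3:-2]], axis=1
        )
        Jv = np.arange(1, nr) + 2
        fwd2 = (-3 * vp[:, Jv] + 4 * vp[:, Jv + 1] - vp[:, Jv + 2]) / (2 * deta)
        bwd2 = (3 * vp[:, Jv] - 4 * vp[:, Jv - 1] + vp[:, Jv - 2]) / (2 * deta)
        conv_v = adv_eta_v * np.where(adv_eta_v >= 0, bwd2, fwd2)

        # xi-padded v: inlet odd, outlet even
        vx = np.concatenate(
            [-v[1:2, 1:-1], -v[0:1, 1:-1], v[:, 1:-1], v[-1:, 1:-1], v[-2:-1, 1:-1]],
            axis=0,
        )
        Iv = np.arange(nz) + 2
        fwd2 = (-3 * vx[Iv, :] + 4 * vx[Iv + 1, :] - vx[Iv + 2, :]) / (2 * dxi)
        bwd2 = (3 * vx[Iv, :] - 4 * vx[Iv - 1, :] + vx[Iv - 2, :]) / (2 * dxi)
        conv_v = conv_v + ubar * np.where(ubar >= 0, bwd2, fwd2)

        return conv_u, conv_v, adv_eta_u, adv_eta_v

    def _pressure_gradient(self, p):
        """Full mapped pressure gradient at interior u-faces and v-faces."""
        g = self.grid
        nz, nr = g.nz, g.nr
        dxi, deta = g.dxi, g.deta
        gpz = (p[1:, :] - p[:-1, :]) / dxi  # at interior u-faces
        pf = 0.5 * (p[1:, :] + p[:-1, :])
        dpde = np.empty_like(pf)
        dpde[:, 1:-1] = (pf[:, 2:] - pf[:, :-2]) / (2 * deta)
        dpde[:, 0] = (pf[:, 1] - pf[:, 0]) / deta
        dpde[:, -1] = (pf[:, -1] - pf[:, -2]) / deta
        a = g.eta_cell[None, :] * g.Rp_face[1:-1, None] / g.R_face[1:-1, None]
        gpz = gpz - a * dpde
        gpr = (p[:, 1:] - p[:, :-1]) / (g.R_cell[:, None] * deta)  # interior v
        return gpz, gpr

    # -- stepping ----------------------------------------------------------

    def _inlet_values(self, inlet_profile, t):
        """u at the inlet face for each eta-center."""
        g = self.grid
        r = g.eta_cell * g.R_face[0]
        return inlet_profile(r, t)

    def step(self, u, v, p, t, dt, inlet_profile, tol, max_picard=40,
             u_prev=None, dt_prev=None):
        g = self.grid
        nz, nr = g.nz, g.nr
        rho = self.fluid.density
        uk, vk, pk = u.copy(), v.copy(), p.copy()
        if u_prev is not None and dt_prev:
            w = dt / dt_prev
            uk = u + w * (u - u_prev[0])
            vk = v + w * (v - u_prev[1])
        uref = max(np.abs(u).max(), np.abs(self._inlet_values(inlet_profile, t + dt)).max(), 1e-12)
        lu_u = self._momentum_lu(dt, "u")
        lu_v = self._momentum_lu(dt, "v")
        inlet_vals = self._inlet_values(inlet_profile, t + dt)
        trace = []
        for it in range(max_picard):
            conv_u, conv_v, *_ = self._convection(uk, vk)
            gpz, gpr = self._pressure_gradient(pk)
            rhs_u = np.zeros((nz + 1, nr))
            rhs_u[1:-1, :] = u[1:-1, :] / dt - conv_u - gpz / rho
            rhs_u[0, :] = inlet_vals
            ustar = lu_u.solve(rhs_u.ravel()).reshape(nz + 1, nr)
            rhs_v = np.zeros((nz, nr + 1))
            rhs_v[:, 1:-1] = v[:, 1:-1] / dt - conv_v - gpr / rho
            vstar = lu_v.solve(rhs_v.ravel()).reshape(nz, nr + 1)
            div = self.Du @ ustar.ravel() + self.Dv @ vstar.ravel()
            phi = self._proj_lu.solve(rho / dt * div)
            unew = ustar - dt / rho * (self.Gu @ phi).reshape(nz + 1, nr)
            vnew = vstar - dt / rho * (self.Gv @ phi).reshape(nz, nr + 1)
            pnew = pk + phi.reshape(nz, nr)
            res = max(np.abs(unew - uk).max(), np.abs(vnew - vk).max()) / uref
            trace.append(res)
            uk, vk, pk = unew, vnew, pnew
            if res <= tol:
                break
        else:
            raise SolverError(
                f"Picard iteration did not reach tol={tol} at t={t:.4g}s "
                f"(last residual {trace[-1]:.3g})",
                residual_trace=trace,
            )
        div_after = np.abs(
            self.Du @ uk.ravel() + self.Dv @ vk.ravel()
        ).max()
        return uk, vk, pk, trace, div_after

    def advective_rate(self, u, v) -> float:
        """Max over cells of |u|/dxi + |adv_eta|/deta (CFL rate, 1/s)."""
        g = self.grid
        etac, etaf = g.eta_cell, g.eta_face
        vbar = 0.25 * (v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:])
        adv_eta_u = (
            vbar - etac[None, :] * g.Rp_face[1:-1, None] * u[1:-1, :]
        ) / g.R_face[1:-1, None]
        ubar = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])
        adv_eta_v = (
            v[:, 1:-1] - etaf[None, 1:-1] * g.Rp_cell[:, None] * ubar
        ) / g.R_cell[:, None]
        rate = np.abs(u).max() / g.dxi
        rate_eta = max(np.abs(adv_eta_u).max(), np.abs(adv_eta_v).max()) / g.deta
        return float(rate + rate_eta)


def _parabolic_profile(inlet: InletCondition) -> Callable:
    def prof(r, t):
        return inlet.profile(r, t)

    return prof


def solve_unsteady(
    grid: TubeGrid,
    fluid: FluidProperties,
    inlet: InletCondition,
    n_cycles: int = 3,
    cfl_max: float = 0.1,
    tol: float = 1e-6,
    n_phase: int = 200,
    inlet_profile: Callable | None = None,
    store_all_cycles: bool = False,
) -> FlowField:
    """Run ``n_cycles`` cardiac cycles from rest; store the final cycle.

    The advective CFL number is kept at or below ``cfl_max`` by adapting
    the time step on a halving ladder; every step's Picard loop iterates
    until the normalized inter-iterate residual drops below ``tol``.
    The first cycles absorb the impulsive start; snapshots (``n_phase``
    uniform phase points) are stored for the final cycle only, and an
    inlet-pressure trace is recorded each cycle for periodicity checks.
    """
    if not 0 <= cfl_max <= 1:
        raise ValidationError("cfl_max must be in (0, 1]")
    solver = AxisymmetricSolver(grid, fluid)
    profile = inlet_profile or _parabolic_profile(inlet)
    T = inlet.period_s
    g = grid
    u = np.zeros((g.nz + 1, g.nr))
    v = np.zeros((g.nz, g.nr + 1))
    p = np.zeros((g.nz, g.nr))
    u[0, :] = solver._inlet_values(profile, 0.0)

    dt_ref = T / n_phase
    t = 0.0
    phase_grid = np.arange(n_phase) / n_phase
    trace = np.full((n_cycles, n_phase), np.nan)
    snaps_u, snaps_v, snaps_p, snap_t, snap_q = [], [], [], [], []
    cfl_hist, res_hist = [], []
    max_div = 0.0
    u_prev = None
    dt_prev = None

    eta = g.eta_cell
    inlet_w = eta  # area weights ~ eta for the inlet annulus
    next_idx = 0  # global phase index
    total_targets = n_cycles * n_phase
    rate = solver.advective_rate(u, v)
    while next_idx < total_targets:
        # time step from the halving ladder; a step is rejected and retried
        # with half the step if the *post-step* advective CFL exceeds the cap
        # (the pre-step field underestimates the rate during transients)
        dt_need = cfl_max / rate if rate > 0 else dt_ref
        k = max(int(np.ceil(np.log2(dt_ref / dt_need))), 0) if dt_need < dt_ref else 0
        while True:
            dt = dt_ref / 2**k
            try:
                un, vn, pn, picard, div_after = solver.step(
                    u, v, p, t, dt, profile, tol, u_prev=u_prev, dt_prev=dt_prev
                )
            except SolverError:
                if k >= 14:
                    raise
                k += 1
                continue
            new_rate = solver.advective_rate(un, vn)
            if dt * new_rate > cfl_max * (1 + 1e-9) and k < 14:
                k += 1
                continue
            break
        u_prev = (u, v)
        u, v, p = un, vn, pn
        rate = new_rate
        t += dt
        max_div = max(max_div, div_after)
        res_hist.append(picard[-1])
        cfl_hist.append(dt * new_rate)
        dt_prev = dt
        # record crossed phase targets
        while next_idx < total_targets and t >= (next_idx + 1) * T / n_phase - 1e-12:
            cyc, ph = divmod(next_idx, n_phase)
            p_in = float(np.sum(p[0, :] * eta) / np.sum(eta))
            trace[cyc, ph] = p_in
            if cyc == n_cycles - 1 or store_all_cycles:
                snaps_u.append(u.copy())
                snaps_v.append(v.copy())
                snaps_p.append(p.copy())
                snap_t.append(t)
                q = float(
                    np.sum(u[0, :] * eta) * 2 * np.pi * g.R_face[0] ** 2 * g.deta
                )
                snap_q.append(q)
            next_idx += 1
    return FlowField(
        grid=grid,
        phase_times=np.asarray(snap_t),
        u=snaps_u,
        v=snaps_v,
        p=snaps_p,
        inlet_flow=np.asarray(snap_q),
        inlet_pressure_trace=trace,
        phase_grid=phase_grid,
        cfl_history=np.asarray(cfl_hist),
        residual_history=np.asarray(res_hist),
        max_divergence=max_div,
        n_cycles=n_cycles,
        period_s=T,
    )


def solve_steady(
    grid: TubeGrid,
    fluid: FluidProperties,
    inlet: InletCondition,
    cfl_max: float = 0.4,
    tol: float = 1e-6,
    steady_tol: float = 1e-5,
    max_time_factor: float = 6.0,
    inlet_profile: Callable | None = None,
) -> FlowField:
    """March a constant-inflow problem to steady state (pseudo-time).

    Runs until the velocity rate of change, scaled by the advective time
    L/U, falls below ``steady_tol`` (or a generous time cap is hit, which
    raises).  Returns a single-snapshot :class:`FlowField`.
    """
    solver = AxisymmetricSolver(grid, fluid)
    profile = inlet_profile or _parabolic_profile(inlet)
    g = grid
    u = np.zeros((g.nz + 1, g.nr))
    v = np.zeros((g.nz, g.nr + 1))
    p = np.zeros((g.nz, g.nr))
    u[0, :] = solver._inlet_values(profile, 0.0)
    uref = max(np.abs(u[0, :]).max(), 1e-12)
    L = g.s1_m - g.s0_m
    t_adv = L / uref
    nu = fluid.kinematic_viscosity
    t_visc = (g.R_face.max()) ** 2 / nu
    t_end = max_time_factor * max(t_adv, t_visc)
    t = 0.0
    dt_prev = None
    res_hist = []
    max_div = 0.0
    adv_rate = solver.advective_rate(u, v)
    while t < t_end:
        dt = min(cfl_max / adv_rate if adv_rate > 0 else t_adv / 20, t_adv / 20)
        halvings = 0
        while True:
            try:
                un, vn, pn, picard, div_after = solver.step(u, v, p, t, dt, profile, tol)
            except SolverError:
                if halvings >= 10:
                    raise
                dt /= 2
                halvings += 1
                continue
            new_adv = solver.advective_rate(un, vn)
            if dt * new_adv > cfl_max * 1.5 and halvings < 10:
                dt /= 2
                halvings += 1
                continue
            break
        settle = np.abs(un - u).max() / dt * (t_adv / uref)
        max_div = max(max_div, div_after)
        res_hist.append(settle)
        u, v, p = un, vn, pn
        adv_rate = new_adv
        t += dt
        dt_prev = dt
        if settle < steady_tol and t > 2 * t_adv:
            break
    else:
        raise SolverError(
            f"steady solve did not settle (last rate {res_hist[-1]:.3g})",
            residual_trace=res_hist,
        )
    eta = g.eta_cell
    q = float(np.sum(u[0, :] * eta) * 2 * np.pi * g.R_face[0] ** 2 * g.deta)
    return FlowField(
        grid=grid,
        phase_times=np.array([t]),
        u=[u],
        v=[v],
        p=[p],
        inlet_flow=np.array([q]),
        inlet_pressure_trace=np.full((1, 1), np.nan),
        phase_grid=np.array([0.0]),
        cfl_history=np.array([]),
        residual_history=np.asarray(res_hist),
        max_divergence=max_div,
        n_cycles=1,
        period_s=np.inf,
    )
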