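"""Planar (2-D) T-junction solver for the flow-split physics.

Same numerics as the axisymmetric tube solver — MAC staggering, backward
Euler + Picard with upwind convection, exact incremental projection — on
a masked Cartesian grid of two axis-aligned channels (artery along x,
fistula/vein up).  Boundary conditions follow the study protocol: both
artery ends carry prescribed parabolic velocity profiles (the distal
artery is a prescribed *outflow* taking a fixed fraction of the proximal
inflow, since distal blood flows away from the junction), the venous
outlet is a zero-pressure free outflow, and all other faces are no-slip
walls.  The planar parabola uses the 3/2 peak-to-mean factor.

Convection is second-order upwind in the bulk and falls back to
first-order within one cell of walls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ..flowbc import BLOOD, FluidProperties, InletCondition
from ..synth import ValidationError
from .axisym import SolverError
from .grids import JunctionGrid

__all__ = ["JunctionFlowField", "solve_junction_steady"]

# u-face / v-face type codes
_INTERIOR, _WALL, _INLET, _OUTLET_DA, _OUTLET_VEIN = 0, 1, 2, 3, 4


@dataclass
class JunctionFlowField:
    grid: JunctionGrid
    u: np.ndarray  # (nx+1, ny)
    v: np.ndarray  # (nx, ny+1)
    p: np.ndarray  # (nx, ny)
    max_divergence: float
    residual_history: np.ndarray

    def boundary_fluxes(self) -> dict[str, float]:
        """Signed volume fluxes (m^2/s per unit depth) through the open
        boundaries; positive = into the domain for the inlet, out of the
        domain for the outlets."""
        g = self.grid
        h = g.h
        q_in = float(self.u[0, :].sum() * h)
        q_da = float(self.u[-1, :].sum() * h)
        lo, hi = g.vein_cols
        q_vein = float(self.v[lo:hi, -1].sum() * h)
        return {"inlet_PA": q_in, "outlet_DA": q_da, "outlet_vein": q_vein}

    def cell_velocity(self):
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc


class _PlanarOps:
    def __init__(self, grid: JunctionGrid, fluid: FluidProperties):
        self.grid = grid
        self.fluid = fluid
        self.nu = fluid.kinematic_viscosity
        g = grid
        nx, ny = g.nx, g.ny
        F = g.fluid
        self.nx, self.ny = nx, ny

        # classify u-faces
        ut = np.full((nx + 1, ny), _WALL, dtype=np.int8)
        ut[1:nx, :][F[:-1, :] & F[1:, :]] = _INTERIOR
        ut[0, F[0, :]] = _INLET
        ut[nx, F[-1, :]] = _OUTLET_DA
        self.ut = ut
        # classify v-faces
        vt = np.full((nx, ny + 1), _WALL, dtype=np.int8)
        vt[:, 1:ny][F[:, :-1] & F[:, 1:]] = _INTERIOR
        lo, hi = g.vein_cols
        vt[lo:hi, ny] = _OUTLET_VEIN
        self.vt = vt

        self.nu_dof = (nx + 1) * ny
        self.nv_dof = nx * (ny + 1)
        self.np_dof = nx * ny
        self._build_ops()

    def _iu(self, i, j):
        return i * self.ny + j

    def _iv(self, i, j):
        return i * (self.ny + 1) + j

    def _ip(self, i, j):
        return i * self.ny + j

    def _build_ops(self):
        g = self.grid
        nx, ny = self.nx, self.ny
        h = g.h
        F = g.fluid
        fi, fj = np.nonzero(F)
        cells = self._ip(fi, fj)
        ncell = self.np_dof

        # divergence over fluid cells
        rows = np.concatenate([cells] * 4)
        cols = np.concatenate(
            [self._iu(fi + 1, fj), self._iu(fi, fj), self._iv(fi, fj + 1), self._iv(fi, fj)]
        )
        vals = np.concatenate(
            [np.full(cells.size, 1 / h), np.full(cells.size, -1 / h)] * 2
        )
        self.Du = sp.csr_matrix(
            (vals[: 2 * cells.size], (rows[: 2 * cells.size], cols[: 2 * cells.size])),
            shape=(ncell, self.nu_dof),
        )
        self.Dv = sp.csr_matrix(
            (vals[2 * cells.size :], (rows[2 * cells.size :], cols[2 * cells.size :])),
            shape=(ncell, self.nv_dof),
        )

        # through-face pressure gradient (zero rows on prescribed faces)
        iu, ju = np.nonzero(self.ut == _INTERIOR)
        r = self._iu(iu, ju)
        Gu = sp.csr_matrix(
            (
                np.concatenate([np.full(r.size, 1 / h), np.full(r.size, -1 / h)]),
                (
                    np.concatenate([r, r]),
                    np.concatenate([self._ip(iu, ju), self._ip(iu - 1, ju)]),
                ),
            ),
            shape=(self.nu_dof, ncell),
        )
        iv, jv = np.nonzero(self.vt == _INTERIOR)
        r = self._iv(iv, jv)
        rows = [r, r]
        cols = [self._ip(iv, jv), self._ip(iv, jv - 1)]
        vals = [np.full(r.size, 1 / h), np.full(r.size, -1 / h)]
        io, jo = np.nonzero(self.vt == _OUTLET_VEIN)
        r = self._iv(io, jo)
        rows.append(r)
        cols.append(self._ip(io, jo - 1))
        vals.append(np.full(r.size, -2 / h))  # ghost = -p: zero face pressure
        Gv = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nv_dof, ncell),
        )
        self.Gu, self.Gv = Gu, Gv

        A = (self.Du @ Gu + self.Dv @ Gv).tolil()
        # solid cells: decouple with identity rows (pressure there unused)
        solid = np.nonzero(~F)
        sidx = self._ip(*solid)
        A[sidx, sidx] = 1.0
        self._proj_lu = splu(A.tocsc())

        self._build_laplacians()

    def _lap(self, types, idx_fn, shape, tangential_axis):
        """5-point Laplacian rows for interior faces with ghost folding.

        Tangential neighbours that sit fully inside the solid fold back
        with a -1 ghost (no-slip wall half a cell away); all other
        neighbours are referenced directly (wall faces hold value 0).
        """
        ii, jj = np.nonzero(types == _INTERIOR)
        r = idx_fn(ii, jj)
        rows, cols, vals = [], [], []
        h2 = self.grid.h**2
        center = np.full(r.size, -4.0 / h2)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = ii + di, jj + dj
            inside = (ni >= 0) & (ni < shape[0]) & (nj >= 0) & (nj < shape[1])
            tang = (tangential_axis == 0 and di != 0) or (
                tangential_axis == 1 and dj != 0
            )
            deep = np.zeros(r.size, bool)
            nin, njn = np.clip(ni, 0, shape[0] - 1), np.clip(nj, 0, shape[1] - 1)
            if tang:
                deep = inside & (types[nin, njn] == _WALL) & self._deep_wall(
                    types, nin, njn
                ) | ~inside
            # fold ghost for deep/missing tangential neighbours
            fold = deep
            ref = inside & ~fold
            rows.append(r[ref])
            cols.append(idx_fn(ni[ref], nj[ref]))
            vals.append(np.full(ref.sum(), 1.0 / h2))
            center = center - fold * (1.0 / h2)  # ghost = -self
        rows.append(r)
        cols.append(r)
        vals.append(center)
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(np.prod(shape), np.prod(shape)),
        ), (ii, jj)

    def _deep_wall(self, types, ni, nj):
        # a WALL face both of whose adjacent cells are solid ("deep")
        F = self.grid.fluid
        nx, ny = self.nx, self.ny
        if types is self.ut:
            left = np.where(ni - 1 >= 0, F[np.clip(ni - 1, 0, nx - 1), nj], False)
            right = np.where(ni < nx, F[np.clip(ni, 0, nx - 1), nj], False)
            return ~(left | right)
        below = np.where(nj - 1 >= 0, F[ni, np.clip(nj - 1, 0, ny - 1)], False)
        above = np.where(nj < ny, F[ni, np.clip(nj, 0, ny - 1)], False)
        return ~(below | above)

    def _build_laplacians(self):
        nx, ny = self.nx, self.ny
        self.Lu, (self._u_ii, self._u_jj) = self._lap(
            self.ut, self._iu, (nx + 1, ny), tangential_axis=1
        )
        self.Lv, (self._v_ii, self._v_jj) = self._lap(
            self.vt, self._iv, (nx, ny + 1), tangential_axis=0
        )
        mu = np.zeros(self.nu_dof)
        mu[self._iu(self._u_ii, self._u_jj)] = 1.0
        self.mask_u = mu
        mv = np.zeros(self.nv_dof)
        mv[self._iv(self._v_ii, self._v_jj)] = 1.0
        self.mask_v = mv
        # boundary relation rows
        bu_rows, bu_cols, bu_vals = [], [], []
        for code in (_WALL, _INLET, _OUTLET_DA):
            ii, jj = np.nonzero(self.ut == code)
            r = self._iu(ii, jj)
            bu_rows.append(r); bu_cols.append(r); bu_vals.append(np.ones(r.size))
        self.Bu = sp.csr_matrix(
            (np.concatenate(bu_vals), (np.concatenate(bu_rows), np.concatenate(bu_cols))),
            shape=(self.nu_dof, self.nu_dof),
        )
        bv_rows, bv_cols, bv_vals = [], [], []
        ii, jj = np.nonzero(self.vt == _WALL)
        r = self._iv(ii, jj)
        bv_rows.append(r); bv_cols.append(r); bv_vals.append(np.ones(r.size))
        io, jo = np.nonzero(self.vt == _OUTLET_VEIN)
        r = self._iv(io, jo)
        bv_rows += [r, r]
        bv_cols += [r, self._iv(io, jo - 1)]
        bv_vals += [np.ones(r.size), -np.ones(r.size)]  # zero-gradient outflow
        self.Bv = sp.csr_matrix(
            (np.concatenate(bv_vals), (np.concatenate(bv_rows), np.concatenate(bv_cols))),
            shape=(self.nv_dof, self.nv_dof),
        )
        self._mom_cache = {}

    def momentum_lu(self, dt, which):
        key = (dt, which)
        if key not in self._mom_cache:
            if which == "u":
                M = sp.diags(self.mask_u / dt) - self.nu * sp.diags(self.mask_u) @ self.Lu + self.Bu
            else:
                M = sp.diags(self.mask_v / dt) - self.nu * sp.diags(self.mask_v) @ self.Lv + self.Bv
            self._mom_cache[key] = splu(M.tocsc())
        return self._mom_cache[key]

    # -- explicit terms --------------------------------------------------

    def convection(self, u, v):
        """Upwind convection at interior u- and v-faces (2nd order in the
        bulk, 1st order adjacent to boundaries)."""
        h = self.grid.h
        nx, ny = self.nx, self.ny

        def upwind(phi, adv, axis, interior_mask):
            # first order
            fwd1 = (np.roll(phi, -1, axis) - phi) / h
            bwd1 = (phi - np.roll(phi, 1, axis)) / h
            # second order
            fwd2 = (-3 * phi + 4 * np.roll(phi, -1, axis) - np.roll(phi, -2, axis)) / (2 * h)
            bwd2 = (3 * phi - 4 * np.roll(phi, 1, axis) + np.roll(phi, 2, axis)) / (2 * h)
            ok2 = interior_mask & np.roll(interior_mask, 1, axis) & np.roll(
                interior_mask, -1, axis
            ) & np.roll(interior_mask, 2, axis) & np.roll(interior_mask, -2, axis)
            d_pos = np.where(ok2, bwd2, bwd1)
            d_neg = np.where(ok2, fwd2, fwd1)
            return np.where(adv >= 0, d_pos, d_neg)

        u_int = self.ut == _INTERIOR
        v_int = self.vt == _INTERIOR
        # v averaged to u-faces
        vpad = np.zeros((nx + 1, ny + 1))
        vpad[:-1] += v
        vpad[1:] += v
        vbar_u = 0.25 * (vpad[:, :-1] + vpad[:, 1:])
        active_u = self.ut != _WALL
        conv_u = u * upwind(u, u, 0, active_u) + vbar_u * upwind(u, vbar_u, 1, active_u)
        # u averaged to v-faces
        upad = np.zeros((nx + 1, ny + 1))
        upad[:, :-1] += u
        upad[:, 1:] += u
        ubar_v = 0.25 * (upad[:-1, :] + upad[1:, :])
        active_v = self.vt != _WALL
        conv_v = ubar_v * upwind(v, ubar_v, 0, active_v) + v * upwind(v, v, 1, active_v)
        return conv_u * u_int, conv_v * v_int

    def pressure_gradient(self, p):
        h = self.grid.h
        gpx = np.zeros((self.nx + 1, self.ny))
        gpx[1:-1, :] = (p[1:, :] - p[:-1, :]) / h
        gpy = np.zeros((self.nx, self.ny + 1))
        gpy[:, 1:-1] = (p[:, 1:] - p[:, :-1]) / h
        return gpx * (self.ut == _INTERIOR), gpy * (self.vt == _INTERIOR)


def _parabola(y, center, halfwidth, mean):
    xi = (y - center) / halfwidth
    return 1.5 * mean * np.clip(1.0 - xi**2, 0.0, None)


def solve_junction_steady(
    grid: JunctionGrid,
    fluid: FluidProperties = BLOOD,
    inlet: InletCondition | None = None,
    v_mean_inlet: float | None = None,
    da_split: float = 0.2,
    cfl_max: float = 0.25,
    tol: float = 1e-6,
    steady_tol: float = 1e-3,
    max_time_factor: float = 20.0,
) -> JunctionFlowField:
    """Steady junction flow with a prescribed distal-artery outflow split.

    ``da_split`` is the fraction of the proximal-artery flow leaving
    through the distal artery (0.2 reproduces the early 80/20 AVF split);
    the remainder exits through the venous outlet.
    """
    if not 0 <= da_split < 1:
        raise ValidationError("da_split must be in [0, 1)")
    if v_mean_inlet is None:
        if inlet is None:
            raise ValidationError("provide an InletCondition or v_mean_inlet")
        v_mean_inlet = float(np.mean(inlet.v_mean(inlet.waveform.times)))
    ops = _PlanarOps(grid, fluid)
    g = grid
    nx, ny = g.nx, g.ny
    h = g.h
    rho = fluid.density
    yc = g.y_cell

    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    in_rows = ops.ut[0, :] == _INLET
    u_in = _parabola(yc, 0.0, g.artery_halfwidth, v_mean_inlet)
    u_in[~in_rows] = 0.0
    q_in = u_in.sum() * h
    out_rows = ops.ut[nx, :] == _OUTLET_DA
    u_out = _parabola(yc, 0.0, g.artery_halfwidth, 1.0)
    u_out[~out_rows] = 0.0
    u_out *= da_split * q_in / max(u_out.sum() * h, 1e-300)
    u[0, :] = u_in
    u[nx, :] = u_out

    uref = max(abs(v_mean_inlet) * 1.5, 1e-12)
    L = (g.nx * h)
    t_adv = L / uref
    nu = fluid.kinematic_viscosity
    t_end = max_time_factor * max(t_adv, (2 * g.artery_halfwidth) ** 2 / nu)
    t = 0.0
    res_hist = []
    max_div = 0.0
    while t < t_end:
        rate = max(np.abs(u).max(), np.abs(v).max()) / h
        dt = min(cfl_max / rate if rate > 0 else t_adv / 20, t_adv / 20)
        halvings = 0
        while True:  # a stalled Picard loop retries with half the step
            lu_u = ops.momentum_lu(dt, "u")
            lu_v = ops.momentum_lu(dt, "v")
            uk, vk, pk = u.copy(), v.copy(), p.copy()
            trace = []
            for it in range(250):
                conv_u, conv_v = ops.convection(uk, vk)
                gpx, gpy = ops.pressure_gradient(pk)
                rhs_u = ops.mask_u.reshape(nx + 1, ny) * (u / dt - conv_u - gpx / rho)
                rhs_u[0, :] = u_in
                rhs_u[nx, :] = u_out
                ustar = lu_u.solve(rhs_u.ravel()).reshape(nx + 1, ny)
                rhs_v = ops.mask_v.reshape(nx, ny + 1) * (v / dt - conv_v - gpy / rho)
                vstar = lu_v.solve(rhs_v.ravel()).reshape(nx, ny + 1)
                div = ops.Du @ ustar.ravel() + ops.Dv @ vstar.ravel()
                phi = ops._proj_lu.solve(rho / dt * div)
                unew = ustar - dt / rho * (ops.Gu @ phi).reshape(nx + 1, ny)
                vnew = vstar - dt / rho * (ops.Gv @ phi).reshape(nx, ny + 1)
                pnew = pk + phi.reshape(nx, ny) * g.fluid
                res = max(np.abs(unew - uk).max(), np.abs(vnew - vk).max()) / uref
                trace.append(res)
                uk, vk, pk = unew, vnew, pnew
                if res <= tol:
                    break
            else:
                if halvings < 8:
                    dt /= 2
                    halvings += 1
                    continue
                raise SolverError(
                    f"junction Picard stalled at t={t:.4g}s", residual_trace=trace
                )
            break
        div_after = np.abs(ops.Du @ uk.ravel() + ops.Dv @ vk.ravel()).max()
        max_div = max(max_div, div_after)
        settle = np.abs(uk - u).max() / dt * (t_adv / uref)
        res_hist.append(settle)
        u, v, p = uk, vk, pk
        t += dt
        if settle < steady_tol and t > 3 * t_adv:
            break
    else:
        raise SolverError(
            f"junction steady solve did not settle (last rate {res_hist[-1]:.3g})",
            residual_trace=res_hist,
        )
    return JunctionFlowField(
        grid=grid, u=u, v=v, p=p, max_divergence=max_div,
        residual_history=np.asarray(res_hist),
    )
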