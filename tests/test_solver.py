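"""Incompressible Navier-Stokes solver: analytic oracles and contracts."""

import numpy as np
import pytest

from avfcfd import synth
from avfcfd.flowbc import BLOOD, FluidProperties, build_inlet
from avfcfd.solver import (
    AxisymmetricSolver,
    build_grid,
    build_junction_grid,
    build_tube_grid,
    check_periodicity,
    grid_convergence_study,
    solve_steady,
    straight_tube_grid,
)
from avfcfd.synth import ValidationError
from .conftest import POISEUILLE_RADIUS_M, POISEUILLE_VPEAK_MMS


class TestGrids:
    def test_refinement_quadruples_cell_count(self, day7_spec):
        counts = {
            lvl: build_tube_grid(day7_spec, lvl).nz * build_tube_grid(day7_spec, lvl).nr
            for lvl in ("coarse", "medium", "fine")
        }
        assert counts["medium"] == 4 * counts["coarse"]
        assert counts["fine"] == 4 * counts["medium"]

    def test_minimum_lumen_transverse_resolution(self, day7_spec):
        grid = build_tube_grid(day7_spec, "coarse")
        assert grid.min_transverse_cells() >= 8

    def test_junction_grid_has_three_open_boundaries(self, day7_spec):
        grid = build_grid(day7_spec, "coarse", topology="planar_junction")
        assert sorted(grid.open_boundaries()) == [
            "inlet_PA",
            "outlet_DA",
            "outlet_vein",
        ]

    def test_unknown_level_and_topology_rejected(self, day7_spec):
        with pytest.raises(ValidationError):
            build_tube_grid(day7_spec, "ultrafine")
        with pytest.raises(ValidationError):
            build_grid(day7_spec, topology="tetrahedral")


class TestPoiseuille:
    def test_velocity_profile_is_parabolic(self, poiseuille_steady):
        field, inlet = poiseuille_steady
        grid = field.grid
        eta = grid.eta_cell
        v_mean = POISEUILLE_VPEAK_MMS / 2 * 1e-3
        analytic = 2 * v_mean * (1 - eta**2)
        mid = field.u[0][grid.nz // 2, :]
        assert np.abs(mid - analytic).max() / analytic.max() < 0.01

    def test_centerline_to_mean_ratio_is_two(self, poiseuille_steady):
        field, _ = poiseuille_steady
        grid = field.grid
        prof = field.u[0][grid.nz // 2, :]
        eta = grid.eta_cell
        v_mean = np.sum(prof * eta) * 2 * grid.deta
        centerline = prof[0] / (1 - eta[0] ** 2)  # extrapolate to the axis
        assert centerline / v_mean == pytest.approx(2.0, rel=0.01)

    def test_mass_conservation_and_divergence(self, poiseuille_steady):
        field, _ = poiseuille_steady
        grid = field.grid
        eta = grid.eta_cell
        q_in = np.sum(field.u[0][0, :] * eta)
        q_out = np.sum(field.u[0][-1, :] * eta)
        assert abs(q_out - q_in) / q_in < 1e-3
        assert field.max_divergence < 1e-8

    def test_pressure_drop_matches_hagen_poiseuille(self, poiseuille_steady):
        field, inlet = poiseuille_steady
        grid = field.grid
        eta = grid.eta_cell
        p_axis = (field.p[0] * eta).sum(axis=1) / eta.sum()
        dp = p_axis[0] - p_axis[-1]
        L_eff = grid.xi_cell[-1] - grid.xi_cell[0]
        v_mean = POISEUILLE_VPEAK_MMS / 2 * 1e-3
        expected = 8 * BLOOD.dynamic_viscosity * L_eff * v_mean / POISEUILLE_RADIUS_M**2
        assert dp == pytest.approx(expected, rel=0.01)

    def test_refined_parabola_stays_exact(self):
        """The discrete system reproduces the parabolic solution to solver
        precision at any resolution (quadratic wall ghost), so refinement
        cannot increase the error."""
        errs = []
        for nr in (8, 16):
            grid = straight_tube_grid(POISEUILLE_RADIUS_M, 2e-3, nz=32, nr=nr)
            inlet = build_inlet(
                synth.synth_waveform(POISEUILLE_VPEAK_MMS, 450.0, 0.0),
                POISEUILLE_RADIUS_M,
            )
            f = solve_steady(grid, BLOOD, inlet, steady_tol=1e-7)
            eta = grid.eta_cell
            ana = 2 * 0.05 * (1 - eta**2)
            errs.append(np.abs(f.u[0][grid.nz // 2] - ana).max() / ana.max())
        assert max(errs) < 1e-5


class TestWomersley:
    def test_profile_matches_bessel_solution(self, womersley_case):
        """Final-cycle velocity profiles match the analytic pulsatile tube
        solution within 3% (max over all stored phases)."""
        field, u_exact, alpha = womersley_case
        assert alpha == pytest.approx(1.0, abs=0.1)
        grid = field.grid
        r = grid.eta_cell * grid.R_face[0]
        i = grid.nz // 2
        u_max, err = 0.0, 0.0
        for k, t in enumerate(field.phase_times):
            ana = u_exact(r, t)
            err = max(err, np.abs(field.u[k][i, :] - ana).max())
            u_max = max(u_max, np.abs(ana).max())
        assert err / u_max < 0.03

    def test_cfl_contract_held_throughout(self, womersley_case):
        field, _, _ = womersley_case
        assert field.cfl_history.max() <= 0.1 + 1e-9

    def test_divergence_free_every_step(self, womersley_case):
        field, _, _ = womersley_case
        assert field.max_divergence < 1e-8


class TestPeriodicity:
    def test_pulsatile_run_settles_monotonically(self, day7_pulsatile):
        field, _, _ = day7_pulsatile
        result = check_periodicity(field, tol=0.01)
        devs = result["deviations"]
        assert devs[1] < devs[0]
        assert result["converged"]

    def test_zero_tolerance_never_converges(self, day7_pulsatile):
        field, _, _ = day7_pulsatile
        assert not check_periodicity(field, tol=0.0)["converged"]

    def test_single_cycle_trace_rejected(self):
        with pytest.raises(ValidationError):
            check_periodicity(np.ones((1, 10)))
        with pytest.raises(ValidationError, match="mismatched|unfilled"):
            check_periodicity(np.full((3, 10), np.nan))


class TestInvariances:
    def test_gauge_invariance_of_pressure(self, poiseuille_steady):
        """Adding a constant to the pressure leaves the velocity update
        unchanged (zero-pressure outlet fixes the gauge)."""
        field, inlet = poiseuille_steady
        grid = field.grid
        solver = AxisymmetricSolver(grid, BLOOD)
        prof = lambda r, t: inlet.profile(r, t)
        u0, v0, p0 = field.u[0], field.v[0], field.p[0]
        dt = 2e-5
        u1, v1, *_ = solver.step(u0, v0, p0, 0.0, dt, prof, tol=1e-10)
        u2, v2, *_ = solver.step(u0, v0, p0 + 250.0, 0.0, dt, prof, tol=1e-10)
        scale = np.abs(u1).max()
        assert np.abs(u1 - u2).max() / scale < 1e-6
        assert np.abs(v1 - v2).max() / scale < 1e-6

    def test_viscosity_doubling_doubles_pressure_drop(self):
        """Stokes-regime linearity: at fixed flow, doubling mu doubles the
        Poiseuille pressure drop."""
        drops = []
        for mu in (4e-3, 8e-3):
            grid = straight_tube_grid(0.3e-3, 1.5e-3, nz=32, nr=8)
            inlet = build_inlet(synth.synth_waveform(60.0, 450.0, 0.0), 0.3e-3)
            fluid = FluidProperties(density=1040.0, dynamic_viscosity=mu)
            f = solve_steady(grid, fluid, inlet, steady_tol=1e-6)
            eta = grid.eta_cell
            p_mean = (f.p[0] * eta).sum(axis=1) / eta.sum()
            drops.append(p_mean[0] - p_mean[-1])
        assert drops[1] / drops[0] == pytest.approx(2.0, rel=0.01)

    def test_time_step_halving_leaves_fields_unchanged(self):
        """Backward-Euler temporal error: halving the CFL-driven time step
        changes the final-cycle velocity field by < 0.5%."""
        R = 0.3e-3
        grid = straight_tube_grid(R, 1.5e-3, nz=32, nr=8)
        inlet = build_inlet(synth.synth_waveform(60.0, 450.0, 0.5, seed=0), R)
        fields = []
        for cfl in (0.1, 0.05):
            from avfcfd.solver import solve_unsteady

            fields.append(
                solve_unsteady(grid, BLOOD, inlet, n_cycles=2, cfl_max=cfl, n_phase=50)
            )
        k = fields[0].peak_systole_index()
        a, b = fields[0].u[k], fields[1].u[k]
        assert np.abs(a - b).max() / np.abs(b).max() < 0.005


class TestGridStudyMechanics:
    def test_identical_fields_give_zero_difference(self, day7_pulsatile, day7_spec):
        field, _, _ = day7_pulsatile
        res = grid_convergence_study(
            day7_spec,
            levels=("a", "b"),
            fields={"a": field, "b": field},
        )
        assert res.velocity_diff_pct["a-vs-b"] == 0.0
        assert res.pressure_diff_pct["a-vs-b"] == 0.0

    def test_fewer_than_two_levels_rejected(self, day7_spec):
        with pytest.raises(ValidationError):
            grid_convergence_study(day7_spec, levels=("coarse",))


class TestJunction:
    def test_prescribed_split_is_recovered(self, junction_steady):
        fx = junction_steady.boundary_fluxes()
        assert fx["outlet_vein"] / fx["inlet_PA"] == pytest.approx(0.80, abs=0.005)
        assert fx["outlet_DA"] / fx["inlet_PA"] == pytest.approx(0.20, abs=0.005)

    def test_junction_mass_balance_and_divergence(self, junction_steady):
        fx = junction_steady.boundary_fluxes()
        assert (fx["outlet_DA"] + fx["outlet_vein"]) / fx["inlet_PA"] == pytest.approx(
            1.0, abs=1e-3
        )
        assert junction_steady.max_divergence < 1e-8

    def test_invalid_split_rejected(self, day7_spec):
        from avfcfd.solver import solve_junction_steady

        grid = build_junction_grid(day7_spec, "coarse")
        with pytest.raises(ValidationError):
            solve_junction_steady(grid, BLOOD, v_mean_inlet=0.1, da_split=1.2)
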