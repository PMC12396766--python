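"""Hemodynamic metrics: WSS, TAWSS, OSI, Q-criterion, profiles, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avfcfd import metrics
from avfcfd.synth import ValidationError
from .conftest import POISEUILLE_RADIUS_M, POISEUILLE_VPEAK_MMS

T_CARDIAC = 60.0 / 450.0


def _phases(n=200, T=T_CARDIAC):
    return np.arange(n) / n * T


class TestWallShearStress:
    def test_poiseuille_wss_closed_form(self, poiseuille_steady):
        """WSS = 4 mu Q / (pi R^3) for fully developed tube flow."""
        field, inlet = poiseuille_steady
        rec = metrics.wall_shear_stress(field)
        Q = inlet.flow_rate_m3s(0.0)
        expected = 4 * 4e-3 * Q / (np.pi * POISEUILLE_RADIUS_M**3)
        mid = rec.tau[10:-10, -1]
        assert np.abs(mid / expected - 1).max() < 0.01

    def test_quiescent_fluid_has_zero_wss(self, poiseuille_steady):
        field, _ = poiseuille_steady
        import copy

        still = copy.copy(field)
        still.u = [np.zeros_like(field.u[0])]
        still.v = [np.zeros_like(field.v[0])]
        rec = metrics.wall_shear_stress(still)
        assert np.all(rec.tau == 0.0)

    def test_wss_linearity_in_flow(self, poiseuille_steady):
        """Doubling the velocity field doubles WSS pointwise (Stokes)."""
        field, _ = poiseuille_steady
        import copy

        doubled = copy.copy(field)
        doubled.u = [2 * field.u[0]]
        doubled.v = [2 * field.v[0]]
        r1 = metrics.wall_shear_stress(field)
        r2 = metrics.wall_shear_stress(doubled)
        assert np.allclose(r2.tau, 2 * r1.tau, rtol=1e-12)


class TestTawss:
    def test_constant_signal(self):
        t = _phases()
        tau = np.full((1, t.size), 3.3)
        assert metrics.tawss(tau, t, T_CARDIAC)[0] == pytest.approx(3.3, rel=1e-12)

    def test_rectified_sine_average(self):
        """mean of |sin| over a period is 2/pi."""
        t = _phases(400)
        tau = 5.0 * np.sin(2 * np.pi * t / T_CARDIAC)
        got = metrics.tawss(tau[None, :], t, T_CARDIAC)[0]
        assert got == pytest.approx(5.0 * 2 / np.pi, rel=1e-3)

    def test_single_phase_rejected(self):
        with pytest.raises(ValidationError):
            metrics.tawss(np.ones((1, 1)), np.array([0.0]), T_CARDIAC)

    def test_steady_run_tawss_equals_instantaneous(self, poiseuille_steady):
        field, _ = poiseuille_steady
        rec = metrics.wall_shear_stress(field)
        assert np.allclose(rec.tawss, np.abs(rec.tau[:, 0]), atol=1e-9)


class TestOsi:
    def test_full_reversal_sine(self):
        t = _phases()
        tau = np.sin(2 * np.pi * t / T_CARDIAC)
        assert metrics.osi(tau[None, :], t, T_CARDIAC)[0] == pytest.approx(0.5, abs=1e-12)

    def test_unidirectional_signal(self):
        t = _phases()
        tau = 1.0 + 0.5 * np.sin(2 * np.pi * t / T_CARDIAC)
        assert metrics.osi(tau[None, :], t, T_CARDIAC)[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_quarter_reversal(self):
        """tau = +1 for 3/4 of the cycle, -1 for 1/4: direct integration
        of the definition gives OSI = (1 - 1/2)/2 = 1/4."""
        n = 8000
        t = _phases(n)
        tau = np.where(t < 0.75 * T_CARDIAC, 1.0, -1.0)
        assert metrics.osi(tau[None, :], t, T_CARDIAC)[0] == pytest.approx(0.25, abs=2e-3)

    def test_zero_signal_warns_and_returns_zero(self):
        t = _phases()
        with pytest.warns(UserWarning, match="zero"):
            out = metrics.osi(np.zeros((1, t.size)), t, T_CARDIAC)
        assert out[0] == 0.0

    @given(
        amps=st.lists(st.floats(-10, 10), min_size=1, max_size=5),
        phases=st.lists(st.floats(0, 2 * np.pi), min_size=1, max_size=5),
        offset=st.floats(-5, 5),
    )
    @settings(max_examples=60, deadline=None)
    def test_osi_bounds_property(self, amps, phases, offset):
        """OSI of arbitrary band-limited periodic shear lies in [0, 0.5]."""
        t = _phases(128)
        tau = np.full_like(t, offset)
        for k, (a, ph) in enumerate(zip(amps, phases), start=1):
            tau = tau + a * np.sin(2 * np.pi * k * t / T_CARDIAC + ph)
        val = metrics.osi(tau[None, :], t, T_CARDIAC)[0]
        assert 0.0 <= val <= 0.5

    def test_scaling_invariance_and_tawss_linearity(self):
        rng = np.random.default_rng(5)
        t = _phases(100)
        tau = rng.normal(size=(4, t.size))
        for scale in (3.0, 0.2):
            assert np.allclose(
                metrics.osi(scale * tau, t, T_CARDIAC), metrics.osi(tau, t, T_CARDIAC)
            )
            assert np.allclose(
                metrics.tawss(scale * tau, t, T_CARDIAC),
                scale * metrics.tawss(tau, t, T_CARDIAC),
            )


class TestQCriterion:
    def test_rigid_rotation(self):
        n = 33
        x = np.linspace(-1, 1, n)
        X, Y = np.meshgrid(x, x, indexing="ij")
        omega = 1.7
        q = metrics.q_criterion_planar(-omega * Y, omega * X, x[1] - x[0])
        assert np.allclose(q[4:-4, 4:-4], omega**2, rtol=1e-9)

    def test_pure_shear_and_translation_vanish(self):
        n = 33
        x = np.linspace(-1, 1, n)
        X, Y = np.meshgrid(x, x, indexing="ij")
        q_shear = metrics.q_criterion_planar(2.5 * Y, np.zeros_like(X), x[1] - x[0])
        q_trans = metrics.q_criterion_planar(np.full_like(X, 0.7), np.full_like(X, -0.3), x[1] - x[0])
        assert np.abs(q_shear[2:-2, 2:-2]).max() < 1e-9
        assert np.abs(q_trans).max() < 1e-12

    def test_poiseuille_tube_is_strain_dominated(self, poiseuille_steady):
        field, _ = poiseuille_steady
        q = metrics.q_criterion(field, 0)
        assert q[5:-5, :].max() <= 1e-6  # pure shear: no vortical cores

    def test_junction_flow_contains_a_vortex(self, junction_steady):
        q = metrics.q_criterion(junction_steady)
        assert q.max() > 0.0  # rotation-dominated region at the junction


class TestProfilesAndSplits:
    def test_max_at_least_average_everywhere(self, day7_pulsatile):
        field, _, _ = day7_pulsatile
        for name in ("speed", "pressure", "tawss", "osi"):
            prof = metrics.metric_profile(field, name)
            assert np.all(prof.max_val + 1e-12 >= prof.avg_val)

    def test_stenotic_tawss_peaks_near_the_throat(self, day7_pulsatile):
        field, spec, _ = day7_pulsatile
        prof = metrics.metric_profile(field, "tawss")
        s_peak = prof.s_mm[np.argmax(prof.max_val)]
        assert abs(s_peak - spec.fistula.stenosis.center_s) < 0.5

    def test_windowed_average_of_constant_profile(self):
        s = np.linspace(0, 4, 81)
        prof = metrics.MetricProfile("const", s, np.full(81, 2.0), np.full(81, 2.0))
        assert prof.windowed_average(0, 4) == pytest.approx(2.0)

    def test_flow_split_junction(self, junction_steady):
        frac = metrics.flow_split(junction_steady)
        assert frac["AVF"] == pytest.approx(0.80, abs=0.005)
        assert sum(frac.values()) == pytest.approx(1.0, abs=0.005)

    def test_flow_split_single_outlet_tube(self, poiseuille_steady):
        field, _ = poiseuille_steady
        assert metrics.flow_split(field)["outlet"] == pytest.approx(1.0, abs=1e-6)


class TestPressureDrop:
    def test_linear_profile_half_distance(self):
        s = np.linspace(0, 10, 101)
        p = 100 - 10 * s
        assert metrics.pressure_drop_localization(s, p, 5.0) == pytest.approx(0.5)

    def test_uniform_tube_fraction_is_distance_over_length(self, poiseuille_steady):
        field, _ = poiseuille_steady
        s, p = metrics.centerline_pressure(field, 0)
        L = s[-1] - s[0]
        d = 0.4 * L
        got = metrics.pressure_drop_localization(s, p, d, s_start=s[0])
        assert got == pytest.approx(0.4, abs=0.02)

    def test_stenosis_concentrates_the_drop(self, day7_spec):
        """Series-resistance oracle on the analytic day-7 radius profile:
        the stenosis inside the first 1.5 mm concentrates more than the
        proportional share of the total drop."""
        from avfcfd import synth as _synth

        s = np.linspace(0.0, 8.0, 2001)
        r = day7_spec.avf_diameter(s) / 2
        dens = 1.0 / r**4
        cum = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(s))])
        frac = np.interp(1.5, s, cum) / cum[-1]
        assert frac > 1.5 / 8.0

    def test_zero_total_drop_rejected(self):
        with pytest.raises(ValidationError):
            metrics.pressure_drop_localization([0, 1, 2], [5.0, 5.0, 5.0], 1.0)


class TestTawssDiameterCorrelation:
    def test_poiseuille_power_law_exponent(self):
        """Synthetic Poiseuille data: TAWSS ∝ d^-3 at constant flow."""
        rng = np.random.default_rng(0)
        d = rng.uniform(0.3, 1.7, size=60)
        tawss = 4 * 4e-3 * 2.2e-8 / (np.pi * (d / 2 * 1e-3) ** 3)
        fit = metrics.correlate_tawss_diameter(tawss, d)
        assert fit["exponent"] == pytest.approx(-3.0, abs=0.01)
        assert fit["r_squared"] > 0.999

    def test_constant_tawss_zero_exponent(self):
        d = np.linspace(0.4, 1.5, 30)
        fit = metrics.correlate_tawss_diameter(np.full(30, 2.0), d)
        assert fit["exponent"] == pytest.approx(0.0, abs=1e-9)

    def test_solver_fields_show_inverse_relationship(self, day7_pulsatile):
        field, spec, _ = day7_pulsatile
        rec = metrics.wall_shear_stress(field)
        sel = (rec.s_mm > 0.3) & (rec.s_mm < 4.0)
        d = spec.avf_diameter(rec.s_mm[sel])
        fit = metrics.correlate_tawss_diameter(rec.tawss[sel], d)
        assert fit["exponent"] < -1.0

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValidationError):
            metrics.correlate_tawss_diameter([1, 2, 3], [1, 2, 3])
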