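"""Synthetic geometry, phantom and waveform generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avfcfd import synth
from avfcfd.synth import ValidationError


class TestGeometryPresets:
    @pytest.mark.parametrize(
        "preset, stats",
        [("day7", synth.REFERENCE_DIAMETERS["day7"]), ("day21", synth.REFERENCE_DIAMETERS["day21"])],
    )
    def test_preset_reproduces_published_window_statistics(self, preset, stats):
        """Windowed mean/min/max of the analytic diameter law match the
        published per-segment table within rounding (0.005 mm)."""
        spec = synth.make_avf_geometry(preset)
        s = np.linspace(0.0, 4.0, 8001)
        d = spec.avf_diameter(s)
        w2 = s <= 2.0
        checks = {
            "avf2_mean": np.trapezoid(d[w2], s[w2]) / 2.0,
            "avf2_min": d[w2].min(),
            "avf2_max": d[w2].max(),
            "avf4_mean": np.trapezoid(d, s) / 4.0,
            "avf4_min": d.min(),
            "avf4_max": d.max(),
        }
        for key, val in checks.items():
            assert val == pytest.approx(stats[key], abs=5e-3), key

    def test_preset_artery_diameters_and_throat(self):
        d7 = synth.make_avf_geometry("day7")
        assert d7.proximal_artery.diameter == 0.29
        assert d7.fistula.stenosis.min_diameter == 0.46
        assert d7.vein.max_diameter == 1.07
        d21 = synth.make_avf_geometry("day21")
        assert d21.proximal_artery.diameter == 0.39
        assert d21.fistula.stenosis.min_diameter == 0.31
        assert d21.vein.max_diameter == 1.71
        # throat diameter is hit exactly at the stenosis center
        for spec in (d7, d21):
            c = spec.fistula.stenosis.center_s
            assert spec.avf_diameter(c) == pytest.approx(
                spec.fistula.stenosis.min_diameter, abs=1e-5
            )

    def test_custom_uniform_tube_has_constant_radius(self):
        spec = synth.make_avf_geometry(
            "custom",
            proximal_artery=synth.Segment(0.88, 3.0),
            distal_artery=synth.Segment(0.88, 3.0),
            fistula=synth.Fistula(0.88, 4.0, stenosis=None),
            vein=synth.Vein(0.88, 0.88, 4.0),
        )
        s = np.linspace(-2, 8, 500)
        assert np.allclose(spec.avf_diameter(s), 0.88, atol=1e-12)

    def test_radius_law_is_continuous(self):
        for preset in ("day7", "day21"):
            spec = synth.make_avf_geometry(preset)
            s = np.linspace(-2.0, 8.0, 20001)
            d = spec.avf_diameter(s)
            assert np.abs(np.diff(d)).max() < 2e-3  # no jumps at 0.5 um scale

    def test_invalid_overrides_raise_validation_errors(self):
        with pytest.raises(ValidationError, match="diameter"):
            synth.Segment(-0.1, 3.0)
        with pytest.raises(ValidationError, match="min_diameter"):
            synth.Fistula(0.5, 4.0, synth.Stenosis(1.0, 0.6, 0.5))
        with pytest.raises(ValidationError, match="anastomosis_angle"):
            synth.make_avf_geometry("day7", anastomosis_angle=190.0)
        with pytest.raises(ValidationError):
            synth.make_avf_geometry("nosuchday")


class TestRadiusProfile:
    def test_gaussian_stenosis_recovers_one_width_from_center(self, day7_spec):
        """One stenosis width away from the throat the lumen is back to
        within 1% of the local nominal (Gaussian sigma = width/3)."""
        st_ = day7_spec.fistula.stenosis
        near = day7_spec.avf_diameter(st_.center_s + st_.width)
        # nominal: same law with the dip removed
        import dataclasses

        no_sten = dataclasses.replace(
            day7_spec,
            fistula=synth.Fistula(day7_spec.fistula.nominal_diameter, 4.0, None),
            _law=day7_spec._law,
        )
        nominal = no_sten.avf_diameter(st_.center_s + st_.width)
        assert near == pytest.approx(nominal, rel=0.013)

    def test_profile_frame_layout_and_sign_convention(self, day7_spec):
        prof = synth.radius_profile(day7_spec, ds=0.05)
        assert list(prof.columns) == ["s_mm", "area_mm2", "diameter_mm", "branch"]
        assert (prof.loc[prof.branch.isin(["PA", "DA"]), "s_mm"] <= 0).all()
        assert (prof.loc[prof.branch.isin(["AVF", "vein"]), "s_mm"] >= 0).all()
        d = prof["diameter_mm"].to_numpy()
        assert np.allclose(prof["area_mm2"], np.pi * (d / 2) ** 2)

    def test_too_coarse_ds_raises(self, day7_spec):
        with pytest.raises(ValidationError, match="shortest segment"):
            synth.radius_profile(day7_spec, ds=5.0)


class TestVoxelizePhantom:
    def test_cylinder_voxel_count_matches_analytic_volume(self):
        spec = synth.make_avf_geometry(
            "custom",
            proximal_artery=synth.Segment(0.74, 2.0),
            distal_artery=synth.Segment(0.74, 2.0),
            fistula=synth.Fistula(0.74, 4.0, None),
            vein=synth.Vein(0.74, 0.74, 2.0),
        )
        vol = synth.voxelize_phantom(spec, spacing_um=72.0, noise_sd=0.0)
        n_in = int((vol.values > 300).sum())
        # artery tube + fistula tube - their overlap at the T-junction
        r = 0.37
        v_art = np.pi * r**2 * 4.0
        v_fist = np.pi * r**2 * 6.0
        v_overlap = (16.0 / 3.0) * r**3  # Steinmetz solid of equal cylinders
        expected = (v_art + v_fist - v_overlap) / vol.spacing_mm**3
        assert n_in == pytest.approx(expected, rel=0.10)

    def test_noise_free_phantom_is_binary_valued(self, day7_spec):
        vol = synth.voxelize_phantom(day7_spec, noise_sd=0.0)
        assert set(np.unique(vol.values)) == {0.0, 650.0}

    def test_same_seed_reproduces_noisy_volume(self, day7_spec):
        a = synth.voxelize_phantom(day7_spec, noise_sd=25.0, seed=7)
        b = synth.voxelize_phantom(day7_spec, noise_sd=25.0, seed=7)
        assert np.array_equal(a.values, b.values)
        c = synth.voxelize_phantom(day7_spec, noise_sd=25.0, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_coarse_spacing_is_rejected(self, day7_spec):
        # day-7 minimum lumen is the 0.29 mm artery: > 3 voxels needed
        with pytest.raises(ValidationError, match="finer|spacing"):
            synth.voxelize_phantom(day7_spec, spacing_um=150.0)

    def test_hu_window_preconditions(self, day7_spec):
        with pytest.raises(ValidationError):
            synth.voxelize_phantom(day7_spec, hu_vessel=200.0)
        with pytest.raises(ValidationError):
            synth.voxelize_phantom(day7_spec, hu_background=400.0)


class TestWaveform:
    def test_zero_pulsatility_is_constant(self):
        wf = synth.synth_waveform(100.0, 450.0, 0.0)
        assert np.all(wf.values == 100.0)

    def test_murine_heart_rate_period(self):
        wf = synth.synth_waveform(80.0, heart_rate=450.0)
        assert wf.period_s == pytest.approx(60.0 / 450.0, abs=1e-12)
        assert wf.period_s == pytest.approx(0.1333, abs=5e-5)

    @pytest.mark.parametrize("pulsatility", [0.2, 0.5, 0.8])
    def test_peak_and_trough_follow_pulsatility(self, pulsatility):
        wf = synth.synth_waveform(100.0, 450.0, pulsatility, seed=3)
        assert wf.values.max() == pytest.approx(100.0, rel=1e-3)
        assert wf.values.min() >= 100.0 * (1 - pulsatility) - 1e-9
        assert np.all(wf.values > 0)

    def test_seed_determinism(self):
        a = synth.synth_waveform(100.0, 450.0, 0.5, seed=11)
        b = synth.synth_waveform(100.0, 450.0, 0.5, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_reversing_pulsatility_rejected(self):
        with pytest.raises(ValidationError, match="pulsatility"):
            synth.synth_waveform(100.0, 450.0, 1.0)

    @given(
        peak=st.floats(10.0, 500.0),
        pulsatility=st.floats(0.0, 0.95),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=30, deadline=None)
    def test_waveform_bounds_property(self, peak, pulsatility, seed):
        wf = synth.synth_waveform(peak, 450.0, pulsatility, seed=seed)
        assert wf.values.max() <= peak * (1 + 1e-9)
        assert wf.values.min() >= peak * (1 - pulsatility) - 1e-9


def test_geometry_spec_dict_round_trip():
    """Custom specs serialize to plain key/value form and rebuild with an
    identical diameter law (the config-file interface)."""
    spec = synth.make_avf_geometry(
        "custom",
        proximal_artery=synth.Segment(0.3, 2.0),
        distal_artery=synth.Segment(0.3, 2.0),
        fistula=synth.Fistula(0.7, 4.0, synth.Stenosis(1.0, 0.4, 0.8)),
        vein=synth.Vein(0.7, 0.9, 2.0),
    )
    back = synth.GeometrySpec.from_dict(spec.to_dict())
    s = np.linspace(-1, 6, 200)
    assert np.allclose(back.avf_diameter(s), spec.avf_diameter(s))
    assert all(
        not isinstance(v, np.floating) for v in spec.to_dict()["vein"].values()
    )


def test_record_cycles_spans_requested_duration():
    wf = synth.synth_waveform(100.0, 450.0, 0.5)
    rec = synth.record_cycles(wf, 3, noise_sd=2.0, seed=0)
    assert rec.n_cycles == pytest.approx(3.0, abs=0.01)
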