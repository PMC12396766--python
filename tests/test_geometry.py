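"""Centerline extraction, diameter profiling, resistance."""

import numpy as np
import pytest

from avfcfd import geometry, imaging, synth
from avfcfd.synth import ValidationError


def _tube_mask(nx=80, r_vox=6, spacing_um=100.0):
    """Straight tube along x with circular cross-section, padded."""
    ny = 2 * r_vox + 9
    a = np.zeros((nx, ny, ny), bool)
    ii = np.indices((nx, ny, ny))
    c = ny // 2
    a[(ii[0] >= 4) & (ii[0] < nx - 4) & ((ii[1] - c) ** 2 + (ii[2] - c) ** 2 <= r_vox**2)] = True
    return imaging.LumenMask(a, spacing_um, (0.0, 0.0, 0.0))


def _fake_endpoints(mask):
    """Endpoints for a straight tube: treat both ends as PA/'vein' and a
    mid-wall point as DA (the junction machinery needs three labels)."""
    xs, ys, zs = np.nonzero(mask.values)
    c = int(np.median(ys))
    return {
        "PA": (int(xs.min()), c, c),
        "vein": (int(xs.max()), c, c),
        "DA": (int(np.median(xs)), int(ys.max()), c),
    }


class TestCenterline:
    def test_straight_tube_centerline_stays_on_axis(self, day7_mask):
        mask, lm = day7_mask
        cl = geometry.extract_centerline(mask, lm)
        # the proximal artery of the phantom lies exactly on the x-axis
        pa = cl.select("PA")
        interior = pa.s < -0.5  # away from the junction blend
        dev = np.linalg.norm(pa.points[interior][:, 1:], axis=1)
        assert dev.max() < mask.spacing_mm

    def test_straight_tube_arc_length_matches_construction(self):
        mask = _tube_mask()
        ep = _fake_endpoints(mask)
        # direct two-point trace along the tube
        cl = geometry.extract_centerline(mask, ep)
        pa_plus_avf = cl.arc_length("PA") + cl.arc_length("AVF")
        expected = (mask.values.any(axis=(1, 2)).sum() - 1) * mask.spacing_mm
        assert pa_plus_avf == pytest.approx(expected, abs=2 * mask.spacing_mm)

    def test_bent_path_longer_than_euclidean_distance(self, day7_mask):
        mask, lm = day7_mask
        cl = geometry.extract_centerline(mask, lm)
        # PA end -> vein end goes around the 90 degree junction
        p_start = cl.select("PA").points[0]
        p_end = cl.select("AVF").points[-1]
        path_len = cl.arc_length("PA") + cl.arc_length("AVF")
        assert path_len > np.linalg.norm(p_end - p_start) * 1.2

    def test_anastomosis_is_the_branch_point(self, day7_mask):
        mask, lm = day7_mask
        cl = geometry.extract_centerline(mask, lm)
        avf = cl.select("AVF")
        # extrapolating the fistula path back to s = 0 lands on the
        # phantom's anastomosis (the coordinate origin)
        origin = avf.points[0] - avf.tangents[0] * avf.s[0]
        assert np.linalg.norm(origin) < 3 * mask.spacing_mm

    def test_disconnected_endpoints_raise(self):
        mask = _tube_mask()
        a = mask.values.copy()
        a[40, :, :] = False  # cut the tube
        cut = imaging.LumenMask(a, mask.spacing_um, mask.origin_mm)
        with pytest.raises(ValidationError, match="components"):
            geometry.extract_centerline(cut, _fake_endpoints(mask))


class TestCrossSectionProfile:
    def test_uniform_cylinder_diameter_recovered(self):
        mask = _tube_mask(r_vox=6)  # diameter 1.2 mm at 100 um spacing
        cl = geometry.extract_centerline(mask, _fake_endpoints(mask))
        prof = geometry.cross_section_profile(cl.select("PA", "AVF"), mask)
        interior = (prof.s > -2.5) & (prof.s < 2.5)
        d = prof.diameter_mm[interior]
        assert np.all(np.abs(d - 1.25) <= 1.5 * mask.spacing_mm)

    def test_day7_phantom_minimum_matches_throat(self, day7_mask):
        """Voxelize -> segment -> profile recovers the 0.46 mm stenosis
        throat within one voxel."""
        mask, lm = day7_mask
        cl = geometry.extract_centerline(mask, lm)
        prof = geometry.cross_section_profile(cl, mask)
        avf = prof.window(0.3, 4.0, branches=("AVF",))
        assert avf.diameter_mm.min() == pytest.approx(0.46, abs=mask.spacing_mm)

    def test_elliptical_section_equivalent_diameter(self):
        """Tube with elliptic cross-section (semi-axes 0.4/0.2 mm):
        equivalent diameter is 2 sqrt(ab) = 0.566 mm."""
        nx, ny, nz = 60, 25, 17
        a = np.zeros((nx, ny, nz), bool)
        ii = np.indices((nx, ny, nz))
        sp = 0.05  # mm
        ry, rz = 0.4 / sp, 0.2 / sp
        cy, cz = ny // 2, nz // 2
        ell = ((ii[1] - cy) / ry) ** 2 + ((ii[2] - cz) / rz) ** 2 <= 1.0
        a[(ii[0] >= 4) & (ii[0] < nx - 4) & ell] = True
        mask = imaging.LumenMask(a, sp * 1e3, (0, 0, 0))
        xs = np.nonzero(a.any(axis=(1, 2)))[0]
        ep = {
            "PA": (int(xs.min()), cy, cz),
            "vein": (int(xs.max()), cy, cz),
            "DA": (int(np.median(xs)), cy + int(ry) - 1, cz),
        }
        cl = geometry.extract_centerline(mask, ep)
        prof = geometry.cross_section_profile(cl.select("PA", "AVF"), mask)
        interior = (prof.s > -1.0) & (prof.s < 1.0)
        d_eq = 2 * np.sqrt(0.4 * 0.2)
        assert np.median(prof.diameter_mm[interior]) == pytest.approx(d_eq, abs=0.05)

    def test_profile_resampling_invariance(self, day7_mask):
        mask, lm = day7_mask
        cl = geometry.extract_centerline(mask, lm, ds=0.05)
        prof_a = geometry.cross_section_profile(cl, mask, ds=0.05)
        prof_b = geometry.cross_section_profile(cl, mask, ds=0.1)
        sa = geometry.segment_stats(prof_a, 0.3, 4.0, branches=("AVF",))
        sb = geometry.segment_stats(prof_b, 0.3, 4.0, branches=("AVF",))
        assert sa.mean_mm == pytest.approx(sb.mean_mm, rel=0.01)


class TestSegmentStats:
    def test_constant_profile_collapses(self):
        prof = geometry.DiameterProfile.from_arrays(
            np.linspace(0, 4, 50), np.full(50, 0.8)
        )
        st = geometry.segment_stats(prof, 0.0, 4.0)
        for v in (st.mean_mm, st.min_mm, st.max_mm):
            assert v == pytest.approx(0.8, abs=1e-12)

    def test_empty_window_raises(self):
        prof = geometry.DiameterProfile.from_arrays([0, 1, 2], [0.5, 0.5, 0.5])
        with pytest.raises(ValidationError):
            geometry.segment_stats(prof, 5.0, 6.0)
        with pytest.raises(ValidationError):
            geometry.segment_stats(prof, 2.0, 1.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "old, new, expected",
        [
            (0.74, 0.58, -21.6),  # 2-mm fistula segment narrowing
            (0.46, 0.31, -32.6),  # minimum-diameter narrowing
            (1.07, 1.71, 59.8),  # vein ballooning
            (0.5, 0.5, 0.0),
        ],
    )
    def test_reported_temporal_changes(self, old, new, expected):
        assert geometry.percent_change(old, new) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_old_diameter_rejected(self):
        with pytest.raises(ValidationError):
            geometry.percent_change(0.0, 1.0)


class TestPoiseuilleResistance:
    def test_uniform_tube_closed_form(self):
        s = np.linspace(0, 4, 400)
        prof = geometry.DiameterProfile.from_arrays(s, np.full_like(s, 0.88))
        R = geometry.poiseuille_resistance(prof, mu=4e-3, s_range=(0, 4), branches=None)
        r = 0.44e-3
        expected = 8 * 4e-3 * 4e-3 / (np.pi * r**4)
        assert R == pytest.approx(expected, rel=1e-6)
        assert R == pytest.approx(1.09e9, rel=0.01)

    def test_halving_diameter_is_sixteenfold(self):
        s = np.linspace(0, 4, 200)
        base = geometry.poiseuille_resistance(
            geometry.DiameterProfile.from_arrays(s, np.full_like(s, 0.8)),
            s_range=(0, 4), branches=None,
        )
        half = geometry.poiseuille_resistance(
            geometry.DiameterProfile.from_arrays(s, np.full_like(s, 0.4)),
            s_range=(0, 4), branches=None,
        )
        assert half / base == pytest.approx(16.0, rel=1e-9)

    def test_series_additivity_of_segments(self):
        s = np.linspace(0, 4, 4001)
        d = np.where(s < 2, 0.8, 0.5)
        prof = geometry.DiameterProfile.from_arrays(s, d)
        total = geometry.poiseuille_resistance(prof, s_range=(0, 4), branches=None)
        seg1 = 8 * 4e-3 * 2e-3 / (np.pi * (0.4e-3) ** 4)
        seg2 = 8 * 4e-3 * 2e-3 / (np.pi * (0.25e-3) ** 4)
        assert total == pytest.approx(seg1 + seg2, rel=0.01)

    def test_resistance_monotone_under_dilation(self, day7_spec):
        prof = synth.radius_profile(day7_spec, 0.02)
        avf = prof[prof.branch.isin(["AVF", "vein"])]
        p0 = geometry.DiameterProfile.from_arrays(avf.s_mm, avf.diameter_mm)
        p1 = geometry.DiameterProfile.from_arrays(avf.s_mm, avf.diameter_mm * 1.05)
        r0 = geometry.poiseuille_resistance(p0, s_range=(0, 4), branches=None)
        r1 = geometry.poiseuille_resistance(p1, s_range=(0, 4), branches=None)
        assert r1 < r0
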