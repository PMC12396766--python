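"""Shared fixtures.

Solver runs are expensive, so the canonical cases (steady Poiseuille,
pulsatile day-7/day-21 stenotic tubes, the planar junction) are
session-scoped and shared between the solver, metrics, pipeline and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from avfcfd import synth
from avfcfd.flowbc import BLOOD, build_inlet
from avfcfd.solver import build_tube_grid, solve_steady, solve_unsteady, straight_tube_grid

POISEUILLE_RADIUS_M = 0.37e-3
POISEUILLE_LENGTH_M = 2e-3
POISEUILLE_VPEAK_MMS = 100.0  # centerline peak, mean 50 mm/s


def day_inlet(preset: str, seed: int = 0):
    """Canonical pulsatile inlet for a preset: Doppler-shaped waveform
    rescaled so the time-averaged flow matches the measured AVF flow
    (1.33 / 2.57 mL/min at day 7 / 21)."""
    from avfcfd.pipeline import PRESET_FLOW_MLMIN

    spec = synth.make_avf_geometry(preset)
    wf = synth.synth_waveform(100.0, 450.0, 0.5, seed=seed)
    q = wf.scaled(PRESET_FLOW_MLMIN[preset] / wf.values.mean(), kind="flow_rate")
    radius = float(spec.avf_radius_m()(-spec.inlet_extension * 1e-3))
    return spec, build_inlet(q, radius)


@pytest.fixture(scope="session")
def day7_spec():
    return synth.make_avf_geometry("day7")


@pytest.fixture(scope="session")
def day21_spec():
    return synth.make_avf_geometry("day21")


@pytest.fixture(scope="session")
def day7_phantom(day7_spec):
    """Noise-free day-7 phantom at the scanner's 72 um voxel spacing."""
    vol = synth.voxelize_phantom(day7_spec, spacing_um=72.0, noise_sd=0.0, seed=0)
    landmarks = synth.phantom_landmarks(day7_spec, vol)
    return vol, landmarks


@pytest.fixture(scope="session")
def day7_mask(day7_phantom):
    from avfcfd import imaging

    vol, landmarks = day7_phantom
    mask = imaging.threshold_segment(vol, 300.0, 1000.0)
    return imaging.region_grow(mask, [landmarks["anastomosis"]]), landmarks


@pytest.fixture(scope="session")
def poiseuille_steady():
    """Steady parabolic-inlet flow in a straight tube (analytic oracle)."""
    grid = straight_tube_grid(POISEUILLE_RADIUS_M, POISEUILLE_LENGTH_M, nz=64, nr=16)
    inlet = build_inlet(
        synth.synth_waveform(POISEUILLE_VPEAK_MMS, 450.0, 0.0), POISEUILLE_RADIUS_M
    )
    field = solve_steady(grid, BLOOD, inlet, steady_tol=1e-6)
    return field, inlet


@pytest.fixture(scope="session")
def day7_pulsatile():
    spec, inlet = day_inlet("day7")
    grid = build_tube_grid(spec, "coarse")
    return solve_unsteady(grid, BLOOD, inlet, n_cycles=3), spec, inlet


@pytest.fixture(scope="session")
def day21_pulsatile():
    spec, inlet = day_inlet("day21")
    grid = build_tube_grid(spec, "coarse")
    return solve_unsteady(grid, BLOOD, inlet, n_cycles=3), spec, inlet


@pytest.fixture(scope="session")
def womersley_case():
    """Pulsatile straight-tube run driven by the exact Womersley inlet
    profile at alpha ~ 1 (murine artery at 450 bpm)."""
    from avfcfd.solver.oracles import womersley_solution

    R, L = 0.29e-3, 2e-3
    omega = 2 * np.pi * 7.5
    G0 = 4 * 4e-3 * 0.05 / R**2
    u_exact, alpha = womersley_solution(R, G0, 0.8 * G0, omega)
    grid = straight_tube_grid(R, L, nz=48, nr=16)
    inlet = build_inlet(synth.synth_waveform(100.0, 450.0, 0.0), R)
    field = solve_unsteady(grid, BLOOD, inlet, n_cycles=3, inlet_profile=u_exact)
    return field, u_exact, alpha


@pytest.fixture(scope="session")
def junction_steady(day7_spec):
    from avfcfd.solver import build_junction_grid, solve_junction_steady

    grid = build_junction_grid(day7_spec, "coarse")
    return solve_junction_steady(grid, BLOOD, v_mean_inlet=0.2, da_split=0.2)
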