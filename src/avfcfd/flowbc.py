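"""Doppler-derived boundary conditions: Q = A*V, Womersley number, inlets.

Peak-velocity waveforms are converted to volumetric flow assuming a
parabolic cross-sectional profile (mean velocity = half the centerline
peak for an axisymmetric parabola), which is justified at the low
Womersley numbers (~1) of murine vessels at ~450 bpm.  Raw multi-cycle
records are phase-aligned by cross-correlation and averaged over three
consecutive cycles before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import units
from .synth import FlowWaveform, ValidationError

__all__ = [
    "FluidProperties",
    "InletCondition",
    "cycle_average",
    "mean_from_peak",
    "flow_rate",
    "womersley_number",
    "build_inlet",
    "BLOOD",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: density kg/m^3 and dynamic viscosity Pa*s."""

    density: float = 1040.0
    dynamic_viscosity: float = 4.0e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValidationError("fluid density and viscosity must be > 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


#: Default murine blood properties.
BLOOD = FluidProperties()


@dataclass(frozen=True)
class InletCondition:
    """Time-varying parabolic inlet: flow-rate waveform plus lumen radius.

    ``waveform`` is of ``flow_rate`` kind (mL/min, the reporting unit);
    conversion to SI happens here.  The spatial profile is the
    axisymmetric parabola ``u(r, t) = 2 v_mean(t) (1 - r^2/R^2)``, whose
    disk integral is exactly ``A v_mean(t)``.  For the planar (2-D channel)
    solver the peak-to-mean factor 3/2 is applied internally by the solver.
    """

    waveform: FlowWaveform  # flow-rate waveform, mL/min
    radius_m: float

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValidationError("inlet radius must be > 0")
        if self.waveform.kind != "flow_rate":
            raise ValidationError("InletCondition requires a flow_rate waveform")
        if np.any(self.waveform.values <= 0):
            raise ValidationError(
                "inlet waveform must stay positive: flow reversal at the "
                "artery inlet is outside this model's contract"
            )

    @property
    def area_m2(self) -> float:
        return np.pi * self.radius_m**2

    @property
    def period_s(self) -> float:
        return self.waveform.period_s

    def flow_rate_m3s(self, t):
        return units.mlmin_to_m3s(self.waveform(t))

    def v_mean(self, t):
        """Cross-sectional mean velocity, m/s."""
        return self.flow_rate_m3s(t) / self.area_m2

    def profile(self, r_m, t):
        """Axisymmetric parabolic velocity at radius ``r_m`` (m/s)."""
        r = np.asarray(r_m, float)
        return 2.0 * self.v_mean(t) * np.clip(1.0 - (r / self.radius_m) ** 2, 0.0, None)


def cycle_average(
    raw: FlowWaveform, n_cycles: int = 3, n_phase: int = 200
) -> FlowWaveform:
    """Phase-aligned mean of ``n_cycles`` consecutive cycles of a raw record.

    Cycles are resampled to ``n_phase`` uniform phase points, aligned to
    the first cycle by circular cross-correlation, and averaged.  The
    record must span at least ``n_cycles`` cardiac periods.
    """
    T = raw.period_s
    span = raw.times[-1] - raw.times[0]
    if span + 1e-12 < (n_cycles - 1) * T + T * (1 - 1.0 / n_phase):
        raise ValidationError(
            f"record spans {span / T:.2f} cycles; {n_cycles} are required"
        )
    t0 = raw.times[0]
    phase_t = np.linspace(0.0, T, n_phase, endpoint=False)
    cycles = []
    for k in range(n_cycles):
        tk = t0 + k * T + phase_t
        cycles.append(np.interp(tk, raw.times, raw.values))
    cycles = np.asarray(cycles)
    ref = cycles[0]
    aligned = [ref]
    for c in cycles[1:]:
        corr = np.fft.irfft(np.fft.rfft(ref) * np.conj(np.fft.rfft(c)), n=n_phase)
        shift = int(np.argmax(corr))
        aligned.append(np.roll(c, shift))
    mean = np.mean(aligned, axis=0)
    return FlowWaveform(T, phase_t, mean, raw.kind, raw.heart_rate_bpm)


def mean_from_peak(v_peak):
    """Cross-sectional mean velocity from the Doppler peak, parabolic
    profile assumption: ``v_mean = v_peak / 2`` (same units as input)."""
    if isinstance(v_peak, FlowWaveform):
        return v_peak.scaled(0.5, kind="mean_velocity")
    v = np.asarray(v_peak, float)
    out = v / 2.0
    return out if out.ndim else float(out)


def flow_rate(area_m2: float, v_mean) -> float:
    """Volumetric flow Q = A * V in m^3/s for SI scalar input.

    If ``v_mean`` is a mean-velocity waveform (mm/s), returns a flow-rate
    waveform in mL/min.
    """
    if area_m2 <= 0:
        raise ValidationError("area must be > 0")
    if isinstance(v_mean, FlowWaveform):
        # mm/s -> m/s, times area -> m^3/s -> mL/min
        return v_mean.scaled(
            units.m3s_to_mlmin(area_m2 * 1e-3), kind="flow_rate"
        )
    return area_m2 * v_mean


def womersley_number(
    radius_m: float, heart_rate_bpm: float, fluid: FluidProperties = BLOOD
) -> float:
    """Womersley number alpha = R sqrt(omega rho / mu), omega = 2 pi f."""
    if radius_m <= 0:
        raise ValidationError("radius must be > 0")
    if heart_rate_bpm <= 0:
        raise ValidationError("heart rate must be > 0")
    omega = 2.0 * np.pi * units.bpm_to_hz(heart_rate_bpm)
    return float(radius_m * np.sqrt(omega * fluid.density / fluid.dynamic_viscosity))


def build_inlet(waveform: FlowWaveform, radius_m: float) -> InletCondition:
    """Build a parabolic inlet condition from a waveform.

    ``peak_velocity`` (mm/s) waveforms are halved to mean velocity and
    multiplied by the lumen area (Q = A V); ``mean_velocity`` skips the
    halving; ``flow_rate`` (mL/min) waveforms are used as-is.
    """
    area = np.pi * radius_m**2
    to_q = units.m3s_to_mlmin(area * 1e-3)  # mm/s mean velocity -> mL/min
    if waveform.kind == "peak_velocity":
        q = waveform.scaled(0.5 * to_q, kind="flow_rate")
    elif waveform.kind == "mean_velocity":
        q = waveform.scaled(to_q, kind="flow_rate")
    else:
        q = waveform
    return InletCondition(waveform=q, radius_m=radius_m)
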