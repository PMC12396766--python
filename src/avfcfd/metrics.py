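"""Hemodynamic statistics: WSS, TAWSS, OSI, Q-criterion, profiles, splits.

Definitions follow the standard vascular-CFD conventions:

* wall shear stress  tau = mu * d(u_t)/dn at the wall (signed tangential
  traction; in the axisymmetric/planar reductions the WSS "vector" is the
  signed wall-tangential component),
* TAWSS = (1/T) integral |tau| dt over one cardiac cycle,
* OSI = 1/2 (1 - |integral tau dt| / integral |tau| dt), in [0, 0.5],
  0 for unidirectional shear and 0.5 for complete reversal; identically
  zero shear is assigned OSI = 0 (the definition is 0/0 there),
* Q-criterion = 1/2 (||Omega||^2 - ||S||^2), the second invariant of the
  velocity-gradient tensor; the axisymmetric form includes the azimuthal
  strain v_r/r.

Time quadrature is the trapezoid rule over the stored phase snapshots of
the final cycle, closed periodically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synth import ValidationError
from .solver.axisym import FlowField
from .solver.planar import JunctionFlowField

__all__ = [
    "WallShearRecord",
    "MetricProfile",
    "HemodynamicReport",
    "wall_shear_stress",
    "tawss",
    "osi",
    "q_criterion",
    "q_criterion_planar",
    "metric_profile",
    "flow_split",
    "centerline_pressure",
    "pressure_drop_localization",
    "correlate_tawss_diameter",
]


@dataclass(frozen=True)
class WallShearRecord:
    """Signed wall-tangential shear stress per station and stored phase."""

    s_mm: np.ndarray  # (n_station,) arc length, anastomosis at 0
    times: np.ndarray  # (n_phase,) snapshot times, final cycle
    tau: np.ndarray  # (n_station, n_phase) Pa, signed
    period_s: float

    @property
    def tawss(self) -> np.ndarray:
        return tawss(self.tau, self.times, self.period_s)

    @property
    def osi(self) -> np.ndarray:
        return osi(self.tau, self.times, self.period_s)


@dataclass(frozen=True)
class MetricProfile:
    """Cross-sectional maximum and (area-weighted) average of a metric
    along the centerline."""

    name: str
    s_mm: np.ndarray
    max_val: np.ndarray
    avg_val: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.max_val + 1e-12 < self.avg_val):
            raise ValidationError("per-station max must be >= average")

    def windowed_average(self, s_start: float, s_end: float) -> float:
        m = (self.s_mm >= s_start) & (self.s_mm <= s_end)
        if not m.any():
            raise ValidationError("empty metric window")
        return float(np.trapezoid(self.avg_val[m], self.s_mm[m]) /
                     (self.s_mm[m][-1] - self.s_mm[m][0]))


@dataclass(frozen=True)
class HemodynamicReport:
    """Per-run summary of the hemodynamic state of one timepoint."""

    flow_rates_mlmin: dict  # per branch
    split_fractions: dict  # per outflow branch, sum to 1 within 0.5%
    peak_velocity_mms: float
    peak_velocity_s_mm: float  # arc-length location of the peak
    tawss_avg_4mm_pa: float
    tawss_peak_pa: float
    tawss_peak_s_mm: float
    osi_avg_4mm: float
    osi_peak: float
    osi_peak_s_mm: float
    osi_elevated_extent_mm: float  # arc length with OSI > 0.01 downstream
    resistance_pa_s_m3: float
    pressure_drop_fraction_1p5mm: float
    tawss_diameter_fit: dict  # power-law exponent + R^2

    def __post_init__(self) -> None:
        total = sum(self.split_fractions.values())
        if abs(total - 1.0) > 0.005:
            raise ValidationError(
                f"split fractions sum to {total:.4f} (must be 1 within 0.5%)"
            )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


# --------------------------------------------------------------------------
# wall shear stress
# --------------------------------------------------------------------------


def wall_shear_stress(field: FlowField, grid=None, mu: float = 4.0e-3) -> WallShearRecord:
    """Signed wall-tangential shear stress for an axisymmetric tube run.

    Uses a one-sided second-order (quadratic) fit through the wall and the
    two nearest interior stations of wall-parallel velocity, measured along
    the wall normal; first-order fallback (with a warning) if fewer than
    three transverse cells exist.
    """
    g = grid or field.grid
    nr = g.nr
    Rp = g.Rp_cell
    cos_t = 1.0 / np.sqrt(1.0 + Rp**2)
    # physical distance from the wall to the two nearest eta rows
    d1 = (1.0 - g.eta_cell[nr - 1]) * g.R_cell * cos_t
    d2 = (1.0 - g.eta_cell[nr - 2]) * g.R_cell * cos_t
    taus = []
    for k in range(field.n_phases):
        uc, vc = field.cell_velocity(k)
        ut = (uc + vc * Rp[:, None]) * cos_t[:, None]
        u1 = ut[:, nr - 1]
        if nr >= 3:
            u2 = ut[:, nr - 2]
            dudn = (u1 * d2**2 - u2 * d1**2) / (d1 * d2 * (d2 - d1))
        else:  # pragma: no cover - grids always have nr >= 4
            warnings.warn("fewer than 3 transverse cells: first-order WSS")
            dudn = u1 / d1
        taus.append(mu * dudn)
    s_mm = g.xi_cell * 1e3
    return WallShearRecord(
        s_mm=s_mm,
        times=field.phase_times,
        tau=np.stack(taus, axis=1),
        period_s=field.period_s,
    )


def _closed_cycle(values, times, period_s):
    """Append the periodic wrap point so trapezoid quadrature covers T."""
    t = np.asarray(times, float)
    if t.size < 2:
        if not np.isfinite(period_s):
            # steady snapshot: constant over any notional cycle
            return np.concatenate([values, values], axis=-1), np.array([0.0, 1.0])
        raise ValidationError("time integration needs at least two phases")
    if np.isfinite(period_s):
        t_closed = np.concatenate([t, [t[0] + period_s]])
        v_closed = np.concatenate([values, values[..., :1]], axis=-1)
    else:
        t_closed, v_closed = t, values
    return v_closed, t_closed


def tawss(tau, times, period_s=None) -> np.ndarray:
    """Time-averaged |tau| over one period (trapezoid rule).

    ``tau``: (..., n_phase) signed values or (..., n_comp, n_phase)
    vectors (magnitude taken per phase).
    """
    tau = np.asarray(tau, float)
    if period_s is None:
        period_s = times[-1] - times[0]
    mag = np.abs(tau) if tau.ndim <= 2 else np.linalg.norm(tau, axis=-2)
    v, t = _closed_cycle(mag, times, period_s)
    T = t[-1] - t[0]
    return np.trapezoid(v, t, axis=-1) / T


def osi(tau, times, period_s=None) -> np.ndarray:
    """Oscillatory shear index, Eq. OSI = (1 - |∫tau| / ∫|tau|) / 2.

    Identically zero shear yields OSI = 0 with a warning (0/0 case).
    """
    tau = np.asarray(tau, float)
    if period_s is None:
        period_s = times[-1] - times[0]
    vec = tau.ndim > 2
    v, t = _closed_cycle(tau, times, period_s)
    mean_vec = np.trapezoid(v, t, axis=-1)
    num = np.linalg.norm(mean_vec, axis=-1) if vec else np.abs(mean_vec)
    mag = np.linalg.norm(v, axis=-2) if vec else np.abs(v)
    den = np.trapezoid(mag, t, axis=-1)
    zero = den <= 0
    if np.any(zero):
        warnings.warn("identically zero WSS: OSI defined as 0")
    out = 0.5 * (1.0 - np.where(zero, 1.0, num / np.where(zero, 1.0, den)))
    return np.clip(out, 0.0, 0.5)


# --------------------------------------------------------------------------
# Q-criterion
# --------------------------------------------------------------------------


def q_criterion_planar(u_cell, v_cell, spacing_m) -> np.ndarray:
    """Q from cell-centered planar velocity components (2-D tensor)."""
    ux, uy = np.gradient(u_cell, spacing_m, spacing_m)
    vx, vy = np.gradient(v_cell, spacing_m, spacing_m)
    omega = 0.5 * (uy - vx)
    s_off = 0.5 * (uy + vx)
    norm_omega2 = 2 * omega**2
    norm_s2 = ux**2 + vy**2 + 2 * s_off**2
    return 0.5 * (norm_omega2 - norm_s2)


def q_criterion(field, phase: int = 0) -> np.ndarray:
    """Q-criterion at cell centers for a solver field.

    Axisymmetric fields include the azimuthal strain term v/r in the
    rate-of-strain tensor; planar junction fields use the 2-D tensor.
    """
    if isinstance(field, JunctionFlowField):
        uc, vc = field.cell_velocity()
        q = q_criterion_planar(uc, vc, field.grid.h)
        return np.where(field.grid.fluid, q, 0.0)
    g = field.grid
    u, v = field.u[phase], field.v[phase]
    uc, vc = field.cell_velocity(phase)
    dxi, deta = g.dxi, g.deta
    eta = g.eta_cell
    R = g.R_cell[:, None]
    a = eta[None, :] * g.Rp_cell[:, None] / R
    # staggered-exact derivatives in computational coordinates
    u_xi = (u[1:, :] - u[:-1, :]) / dxi
    v_eta = (v[:, 1:] - v[:, :-1]) / deta
    # centered cross derivatives with symmetry/no-slip ghosts
    uc_pad = np.concatenate([uc[:, :1], uc, -uc[:, -1:]], axis=1)
    u_eta = (uc_pad[:, 2:] - uc_pad[:, :-2]) / (2 * deta)
    vc_pad = np.concatenate([vc[:1, :], vc, vc[-1:, :]], axis=0)
    v_xi = (vc_pad[2:, :] - vc_pad[:-2, :]) / (2 * dxi)
    du_dz = u_xi - a * u_eta
    du_dr = u_eta / R
    dv_dz = v_xi - a * (v[:, 1:] - v[:, :-1]) / deta
    dv_dr = v_eta / R
    r_cell = eta[None, :] * R
    azimuthal = vc / r_cell
    omega = 0.5 * (du_dr - dv_dz)
    s_off = 0.5 * (du_dr + dv_dz)
    norm_omega2 = 2 * omega**2
    norm_s2 = du_dz**2 + dv_dr**2 + azimuthal**2 + 2 * s_off**2
    return 0.5 * (norm_omega2 - norm_s2)


# --------------------------------------------------------------------------
# profiles, splits, pressure drop, correlation
# --------------------------------------------------------------------------


def metric_profile(field: FlowField, metric: str = "speed",
                   phase: int | None = None) -> MetricProfile:
    """Cross-sectional max and area-weighted average along the tube.

    ``metric``: ``speed`` or ``pressure`` (evaluated at ``phase``, default
    peak systole), or ``tawss`` / ``osi`` (wall quantities — max equals
    average in the axisymmetric reduction).
    """
    g = field.grid
    s_mm = g.xi_cell * 1e3
    if metric in ("tawss", "osi"):
        rec = wall_shear_stress(field)
        val = rec.tawss if metric == "tawss" else rec.osi
        return MetricProfile(metric, s_mm, val.copy(), val.copy())
    if phase is None:
        phase = field.peak_systole_index()
    if metric == "speed":
        f = field.speed(phase)
    elif metric == "pressure":
        f = field.p[phase]
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    w = g.eta_cell  # area weight ~ eta for the mapped annulus
    avg = (f * w[None, :]).sum(axis=1) / w.sum()
    return MetricProfile(metric, s_mm, f.max(axis=1), avg)


def flow_split(field) -> dict[str, float]:
    """Outflow fractions of inlet flow per open boundary.

    Raises if the fluxes do not balance within 0.5% (mass-conservation
    contract).
    """
    if isinstance(field, JunctionFlowField):
        fx = field.boundary_fluxes()
        q_in = fx["inlet_PA"]
        fractions = {
            "AVF": fx["outlet_vein"] / q_in,
            "DA": fx["outlet_DA"] / q_in,
        }
    else:
        g = field.grid
        eta = g.eta_cell
        k = field.n_phases - 1
        q_in = float(np.sum(field.u[k][0, :] * eta) * g.R_face[0] ** 2)
        q_out = float(np.sum(field.u[k][-1, :] * eta) * g.R_face[-1] ** 2)
        fractions = {"outlet": q_out / q_in}
    imbalance = abs(sum(fractions.values()) - 1.0)
    if imbalance > 0.005:
        raise ValidationError(
            f"outflow fractions sum to {sum(fractions.values()):.4f}: "
            "mass-conservation violation"
        )
    return fractions


def centerline_pressure(field: FlowField, phase: int | None = None):
    """Cross-sectional average pressure vs arc length (mm, Pa)."""
    prof = metric_profile(field, "pressure", phase)
    return prof.s_mm, prof.avg_val


def pressure_drop_localization(s_mm, p_pa, distance_mm,
                               s_start: float = 0.0) -> float:
    """Fraction of the total pressure drop within ``distance_mm`` of
    ``s_start``: (p(s0) - p(s0 + d)) / (p(s0) - p(end))."""
    s = np.asarray(s_mm, float)
    p = np.asarray(p_pa, float)
    p0 = np.interp(s_start, s, p)
    pd = np.interp(s_start + distance_mm, s, p)
    pe = p[-1]
    total = p0 - pe
    if total == 0:
        raise ValidationError("zero total pressure drop")
    return float((p0 - pd) / total)


def correlate_tawss_diameter(tawss_vals, diameter_mm) -> dict[str, float]:
    """Power-law fit TAWSS ~ d^b via least squares on log-log axes.

    Returns the exponent ``b`` and the coefficient of determination R^2.
    A Poiseuille tube at constant flow gives b = -3.
    """
    t = np.asarray(tawss_vals, float)
    d = np.asarray(diameter_mm, float)
    if t.size < 5:
        raise ValidationError("need at least 5 stations for the fit")
    if np.any(t <= 0) or np.any(d <= 0):
        raise ValidationError("fit requires positive TAWSS and diameter")
    x, y = np.log(d), np.log(t)
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"exponent": float(b), "r_squared": r2}
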