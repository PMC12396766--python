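"""Synthetic inputs: parametric AVF geometries, CT-like phantoms, pulsatile waveforms.

The study system is a murine end-to-side arteriovenous fistula (AVF): the
jugular vein anastomosed onto the carotid artery.  In place of animal
imaging data, this module generates everything the downstream pipeline
consumes:

* :class:`GeometrySpec` — a parametric artery–fistula–vein layout with
  ``day7`` / ``day21`` presets whose analytic diameter law is calibrated to
  the published per-segment diameter statistics (window means and extrema),
* :func:`voxelize_phantom` — a contrast-CT-like voxel volume of the lumen
  (Hounsfield units, isotropic spacing, optional Gaussian noise),
* :func:`synth_waveform` — periodic, strictly positive Doppler-style
  velocity or flow waveforms at a murine heart rate (~450 bpm).

All lengths in this module are millimetres unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "Segment",
    "Stenosis",
    "Fistula",
    "Vein",
    "GeometrySpec",
    "VoxelVolume",
    "FlowWaveform",
    "make_avf_geometry",
    "radius_profile",
    "voxelize_phantom",
    "synth_waveform",
    "record_cycles",
]


class ValidationError(ValueError):
    """A geometry or waveform parameter violates its contract."""


# --------------------------------------------------------------------------
# geometry spec
# --------------------------------------------------------------------------


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class Segment:
    """Straight vessel segment (artery limb)."""

    diameter: float  # mm
    length: float  # mm

    def __post_init__(self) -> None:
        _require(self.diameter > 0, f"segment diameter must be > 0, got {self.diameter}")
        _require(self.length > 0, f"segment length must be > 0, got {self.length}")


@dataclass(frozen=True)
class Stenosis:
    """Gaussian constriction of the fistula radius along arc length.

    ``width`` is the arc-length scale of the constriction; the Gaussian
    standard deviation is ``width / 3`` so the lumen recovers to within
    ~1% of its nominal diameter one ``width`` away from ``center_s``.
    """

    center_s: float  # mm from the anastomosis
    min_diameter: float  # mm at the throat
    width: float  # mm

    def __post_init__(self) -> None:
        _require(self.center_s > 0, f"stenosis center_s must be > 0, got {self.center_s}")
        _require(self.min_diameter > 0, "stenosis min_diameter must be > 0")
        _require(self.width > 0, "stenosis width must be > 0")

    @property
    def sigma(self) -> float:
        return self.width / 3.0


@dataclass(frozen=True)
class Fistula:
    nominal_diameter: float  # mm, lumen near the anastomosis
    length: float  # mm, the analysed AVF window (4 mm in the presets)
    stenosis: Stenosis | None = None

    def __post_init__(self) -> None:
        _require(self.nominal_diameter > 0, "fistula nominal_diameter must be > 0")
        _require(self.length > 0, "fistula length must be > 0")
        if self.stenosis is not None:
            _require(
                self.stenosis.min_diameter < self.nominal_diameter,
                "stenosis min_diameter must be smaller than the fistula nominal_diameter",
            )


@dataclass(frozen=True)
class Vein:
    start_diameter: float  # mm, at the fistula/vein boundary
    max_diameter: float  # mm, ballooned main vein
    length: float  # mm

    def __post_init__(self) -> None:
        _require(self.start_diameter > 0, "vein start_diameter must be > 0")
        _require(self.max_diameter > 0, "vein max_diameter must be > 0")
        _require(self.length > 0, "vein length must be > 0")


@dataclass(frozen=True)
class _ProfileLaw:
    """Internal parameters of the analytic diameter law along the AVF path.

    base(s) = smoothmin(d0 + (asymptote - d0) * logistic((s - s_mid) / w), cap)
    d(s)    = base(s) - depth * exp(-(s - c)^2 / (2 sigma^2))

    ``cap`` freezes the vein at its ballooned diameter (a soft minimum so
    the radius law stays C^1 — the solver's body-fitted mapping
    differentiates it); ``depth`` is set so the throat diameter equals the
    prescribed stenosis minimum exactly.
    """

    d0: float
    asymptote: float
    s_mid: float
    w: float
    cap: float


#: softness (mm) of the vein-diameter cap
_CAP_W = 0.02


def _smooth_cap(raw, cap):
    """C^1 soft minimum of ``raw`` and the constant ``cap``."""
    return cap - _CAP_W * np.logaddexp(0.0, (cap - raw) / _CAP_W)


@dataclass(frozen=True)
class GeometrySpec:
    """Parametric AVF layout consumed by the voxelizer and the solver grids.

    Arc length ``s`` is zero at the anastomosis, negative on the artery
    side and positive along the fistula/vein (the convention of the
    longitudinal diameter-profile plots).
    """

    proximal_artery: Segment
    distal_artery: Segment
    fistula: Fistula
    vein: Vein
    anastomosis_angle: float = 90.0  # degrees between artery and fistula axes
    inlet_extension: float = 2.0  # mm of straight extension ahead of the inlets
    _law: _ProfileLaw | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        _require(
            0.0 < self.anastomosis_angle < 180.0,
            f"anastomosis_angle must be in (0, 180), got {self.anastomosis_angle}",
        )
        _require(self.inlet_extension >= 0, "inlet_extension must be >= 0")
        if self._law is None:
            object.__setattr__(self, "_law", _default_law(self))

    # -- analytic diameter law -------------------------------------------

    def to_dict(self) -> dict:
        """Human-readable key/value form (YAML/JSON-friendly)."""
        from dataclasses import asdict

        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            return float(x) if isinstance(x, (int, float, np.floating)) else x

        d = asdict(self)
        d.pop("_law", None)
        return plain(d)

    @staticmethod
    def from_dict(data: dict) -> "GeometrySpec":
        data = dict(data)
        sten = data.get("fistula", {}).get("stenosis")
        return GeometrySpec(
            proximal_artery=Segment(**data["proximal_artery"]),
            distal_artery=Segment(**data["distal_artery"]),
            fistula=Fistula(
                nominal_diameter=data["fistula"]["nominal_diameter"],
                length=data["fistula"]["length"],
                stenosis=Stenosis(**sten) if sten else None,
            ),
            vein=Vein(**data["vein"]),
            anastomosis_angle=data.get("anastomosis_angle", 90.0),
            inlet_extension=data.get("inlet_extension", 2.0),
        )

    def avf_diameter(self, s):
        """Analytic lumen diameter (mm) along the fistula/vein path, s >= 0.

        For ``s < 0`` the path is the straight inlet extension at the
        fistula's anastomosis diameter (fully developed inflow).
        """
        law = self._law
        s = np.asarray(s, dtype=float)
        smooth = law.asymptote > law.d0

        def base_of(x):
            raw = law.d0 + (law.asymptote - law.d0) * expit((x - law.s_mid) / law.w)
            return _smooth_cap(raw, law.cap) if smooth else raw

        # straight extension upstream of the anastomosis: clamp s to 0 with a
        # soft hinge (0.1 mm) so the radius law stays C^1 across s = 0
        s_eff = 0.1 * np.logaddexp(0.0, s / 0.1)
        base = base_of(s_eff)
        sten = self.fistula.stenosis
        if sten is not None:
            base_c = float(base_of(sten.center_s))
            depth = base_c - sten.min_diameter
            _require(depth > 0, "stenosis min_diameter exceeds the local base diameter")
            base = base - depth * np.exp(-((s - sten.center_s) ** 2) / (2 * sten.sigma**2))
        return base if base.ndim else float(base)

    def avf_radius_m(self) -> Callable[[np.ndarray], np.ndarray]:
        """Radius law r(s) in metres with s in metres (solver interface)."""

        def r_of_s(s_m):
            return np.asarray(self.avf_diameter(np.asarray(s_m) * 1e3)) / 2.0 * 1e-3

        return r_of_s

    def artery_diameter(self, s):
        """Diameter (mm) along the artery, s < 0 proximal, s > 0 distal."""
        s = np.asarray(s, dtype=float)
        d = np.where(s < 0, self.proximal_artery.diameter, self.distal_artery.diameter)
        return d if d.ndim else float(d)

    @property
    def avf_path_length(self) -> float:
        return self.fistula.length + self.vein.length

    @property
    def min_lumen_diameter(self) -> float:
        s = np.linspace(0.0, self.avf_path_length, 2001)
        dmin = float(np.min(self.avf_diameter(s)))
        return min(dmin, self.proximal_artery.diameter, self.distal_artery.diameter)


def _default_law(spec: GeometrySpec) -> _ProfileLaw:
    """Profile law when no calibration targets are given: logistic ballooning
    centred at the fistula/vein boundary, capped at the vein maximum."""
    d0 = spec.fistula.nominal_diameter
    dmax = spec.vein.max_diameter
    if abs(dmax - d0) < 1e-12:
        return _ProfileLaw(d0=d0, asymptote=d0, s_mid=spec.fistula.length, w=1.0, cap=d0)
    return _ProfileLaw(
        d0=d0,
        asymptote=d0 + 2.0 * (dmax - d0),
        s_mid=spec.fistula.length,
        w=1.0,
        cap=dmax,
    )


# --------------------------------------------------------------------------
# presets calibrated to the published per-segment diameter table
# --------------------------------------------------------------------------

#: Published lumen-diameter statistics (mm): per timepoint, artery diameters
#: and the AVF 2-mm / 4-mm window statistics mean (min - max).
REFERENCE_DIAMETERS = {
    "day7": {
        "proximal_artery": 0.29,
        "distal_artery": 0.36,
        "avf2_mean": 0.74,
        "avf2_min": 0.46,
        "avf2_max": 0.95,
        "avf4_mean": 0.88,
        "avf4_min": 0.46,
        "avf4_max": 1.07,
        "vein_max": 1.07,
    },
    "day21": {
        "proximal_artery": 0.39,
        "distal_artery": 0.46,
        "avf2_mean": 0.58,
        "avf2_min": 0.31,
        "avf2_max": 0.96,
        "avf4_mean": 0.86,
        "avf4_min": 0.31,
        "avf4_max": 1.71,
        "vein_max": 1.71,
    },
}

# Stenosis placement bounds per preset (the table gives only the throat
# diameter): the early lesion is short and close to the anastomosis, the
# late lesion elongated and shifted downstream, matching the described
# remodelling.  Within these bounds, placement is calibrated jointly with
# the base-profile shape to the published window statistics.
_STENOSIS_BOUNDS = {
    "day7": {"center_s": (0.5, 1.0), "width": (0.4, 0.9)},
    "day21": {"center_s": (1.1, 2.0), "width": (0.9, 2.2)},
}

_ARTERY_LENGTH = 3.0  # mm per limb
_VEIN_LENGTH = 4.0  # mm


def _window_stats(d_of_s, lo, hi, n=801):
    s = np.linspace(lo, hi, n)
    d = d_of_s(s)
    return float(np.trapezoid(d, s) / (hi - lo)), float(d.min()), float(d.max())


def _calibrate_preset(preset: str) -> tuple[_ProfileLaw, Stenosis]:
    """Fit the free shape parameters of the diameter law (base profile and
    stenosis placement) so the 2-mm and 4-mm window statistics reproduce
    the published values."""
    t = REFERENCE_DIAMETERS[preset]
    cb = _STENOSIS_BOUNDS[preset]
    dmin = t["avf2_min"]
    cap = t["vein_max"]

    def profile(params, s):
        d0, asym, s_mid, w, c, width = params
        sigma = width / 3.0
        base = _smooth_cap(d0 + (asym - d0) * expit((s - s_mid) / w), cap)
        base_c = float(_smooth_cap(d0 + (asym - d0) * expit((c - s_mid) / w), cap))
        depth = base_c - dmin
        return base - depth * np.exp(-((s - c) ** 2) / (2 * sigma**2))

    targets = np.array(
        [t["avf2_mean"], t["avf2_max"], t["avf4_mean"], t["avf4_max"], dmin, dmin]
    )

    def residuals(params):
        f = lambda s: profile(params, s)
        m2, n2, x2 = _window_stats(f, 0.0, 2.0)
        m4, n4, x4 = _window_stats(f, 0.0, 4.0)
        return np.array([m2, x2, m4, x4, n2, n4]) - targets

    lo = [dmin + 0.02, cap, 1.0, 0.1, cb["center_s"][0], cb["width"][0]]
    hi = [2.0, 6.0, 6.0, 3.0, cb["center_s"][1], cb["width"][1]]
    best = None
    for c0 in np.linspace(*cb["center_s"], 3):
        x0 = np.array(
            [t["avf2_mean"] * 1.15, cap * 1.5, 3.0, 0.7, c0, np.mean(cb["width"])]
        )
        sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-13, ftol=1e-13)
        r = np.abs(sol.fun).max()
        if best is None or r < best[0]:
            best = (r, sol.x)
    if best[0] > 4e-3:
        raise RuntimeError(
            f"preset {preset!r} profile calibration missed the published "
            f"statistics (max residual {best[0]:.4f} mm)"
        )
    d0, asym, s_mid, w, c, width = best[1]
    law = _ProfileLaw(d0=d0, asymptote=asym, s_mid=s_mid, w=w, cap=cap)
    sten = Stenosis(center_s=float(c), min_diameter=dmin, width=float(width))
    return law, sten


_PRESET_CACHE: dict[str, tuple[_ProfileLaw, Stenosis]] = {}


def make_avf_geometry(
    preset: Literal["day7", "day21", "custom"] = "day7", **overrides
) -> GeometrySpec:
    """Build a :class:`GeometrySpec` from a named preset.

    ``day7`` and ``day21`` encode the published post-surgery diameter
    statistics; ``custom`` requires the caller to pass every component.
    Keyword overrides replace whole fields (``fistula=``, ``vein=`` ...)
    and are validated like any other spec.
    """
    if preset == "custom":
        try:
            return GeometrySpec(**overrides)
        except TypeError as exc:
            raise ValidationError(str(exc)) from exc
    if preset not in REFERENCE_DIAMETERS:
        raise ValidationError(f"unknown preset {preset!r}; use day7, day21 or custom")
    t = REFERENCE_DIAMETERS[preset]
    if preset not in _PRESET_CACHE:
        _PRESET_CACHE[preset] = _calibrate_preset(preset)
    law, sten = _PRESET_CACHE[preset]
    fields = dict(
        proximal_artery=Segment(t["proximal_artery"], _ARTERY_LENGTH),
        distal_artery=Segment(t["distal_artery"], _ARTERY_LENGTH),
        fistula=Fistula(nominal_diameter=round(law.d0, 4), length=4.0, stenosis=sten),
        vein=Vein(
            start_diameter=round(
                float(
                    _smooth_cap(
                        law.d0
                        + (law.asymptote - law.d0) * expit((4.0 - law.s_mid) / law.w),
                        law.cap,
                    )
                ),
                4,
            ),
            max_diameter=t["vein_max"],
            length=_VEIN_LENGTH,
        ),
    )
    fields.update(overrides)
    try:
        spec = GeometrySpec(**fields, _law=None)
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc
    if not overrides.keys() & {"fistula", "vein"}:
        # overrides that leave the AVF path untouched keep the calibrated law
        spec = replace(spec, _law=law)
    return spec


# --------------------------------------------------------------------------
# ground-truth diameter profile (oracle for the geometry module)
# --------------------------------------------------------------------------


def radius_profile(spec: GeometrySpec, ds: float):
    """Analytic diameter profile sampled every ``ds`` mm.

    Returns a :class:`pandas.DataFrame` with columns ``s_mm``,
    ``diameter_mm``, ``area_mm2`` and ``branch`` (PA / DA / AVF / vein).
    ``s = 0`` at the anastomosis; artery branches carry negative ``s``.
    """
    import pandas as pd

    _require(ds > 0, "ds must be > 0")
    shortest = min(
        spec.proximal_artery.length,
        spec.distal_artery.length,
        spec.fistula.length,
        spec.vein.length,
    )
    if ds > shortest:
        raise ValidationError(
            f"ds = {ds} mm exceeds the shortest segment length ({shortest} mm)"
        )
    rows = []
    for label, length, diam in (
        ("PA", spec.proximal_artery.length, spec.proximal_artery.diameter),
        ("DA", spec.distal_artery.length, spec.distal_artery.diameter),
    ):
        s = -np.arange(0.0, length + ds / 2, ds)[::-1]
        rows.append(
            pd.DataFrame({"s_mm": s, "diameter_mm": diam, "branch": label})
        )
    lf = spec.fistula.length
    s_avf = np.arange(0.0, spec.avf_path_length + ds / 2, ds)
    rows.append(
        pd.DataFrame(
            {
                "s_mm": s_avf,
                "diameter_mm": spec.avf_diameter(s_avf),
                "branch": np.where(s_avf <= lf, "AVF", "vein"),
            }
        )
    )
    out = pd.concat(rows, ignore_index=True)
    out["area_mm2"] = np.pi * (out["diameter_mm"] / 2.0) ** 2
    return out[["s_mm", "area_mm2", "diameter_mm", "branch"]]


# --------------------------------------------------------------------------
# voxelized contrast-CT phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelVolume:
    """CT-like scalar volume in Hounsfield units with isotropic spacing."""

    values: np.ndarray  # (nx, ny, nz) float HU
    spacing_um: float
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        _require(self.spacing_um > 0, "spacing must be > 0")
        _require(
            self.values.ndim == 3 and min(self.values.shape) >= 2,
            "volume must be 3-D with at least 2 voxels per axis",
        )

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1e3

    def voxel_centers(self):
        """Physical voxel-center coordinates (mm) along each axis."""
        sp = self.spacing_mm
        return tuple(
            self.origin_mm[a] + sp * np.arange(self.values.shape[a]) for a in range(3)
        )


def _lumen_distance_test(spec: GeometrySpec, x, y, z):
    """Boolean lumen membership for coordinate arrays (mm, broadcastable)."""
    # artery along x, centered on the origin
    pa, da = spec.proximal_artery, spec.distal_artery
    r_art = np.where(x < 0, pa.diameter, da.diameter) / 2.0
    in_art = (
        (x >= -pa.length)
        & (x <= da.length)
        & (y**2 + z**2 <= r_art**2)
    )
    # fistula/vein along the anastomosis direction in the x-y plane
    ang = np.deg2rad(spec.anastomosis_angle)
    ux, uy = np.cos(ang), np.sin(ang)
    s = x * ux + y * uy
    d_perp2 = (x - s * ux) ** 2 + (y - s * uy) ** 2 + z**2
    s_c = np.clip(s, 0.0, spec.avf_path_length)
    r_f = spec.avf_diameter(s_c) / 2.0
    in_fist = (s >= 0) & (s <= spec.avf_path_length) & (d_perp2 <= r_f**2)
    return in_art | in_fist


def voxelize_phantom(
    spec: GeometrySpec,
    spacing_um: float = 72.0,
    hu_vessel: float = 650.0,
    hu_background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_voxels: int = 4,
) -> VoxelVolume:
    """Voxelize the AVF lumen into a contrast-CT-like HU volume.

    Voxels whose centers fall inside the lumen take ``hu_vessel``; all
    others ``hu_background``; independent Gaussian noise of standard
    deviation ``noise_sd`` is added everywhere (seed-deterministic).
    """
    _require(spacing_um > 0, "spacing must be > 0")
    _require(
        hu_background < 300.0 <= hu_vessel <= 1000.0,
        "need hu_background < 300 <= hu_vessel <= 1000 (contrast segmentation window)",
    )
    sp = spacing_um / 1e3
    dmin = spec.min_lumen_diameter
    if dmin / sp < 3.0:
        raise ValidationError(
            f"spacing {spacing_um} um spans the minimum lumen diameter "
            f"({dmin:.3f} mm) with fewer than 3 voxels; use spacing below "
            f"{dmin / 3 * 1e3:.0f} um"
        )
    ang = np.deg2rad(spec.anastomosis_angle)
    ux, uy = np.cos(ang), np.sin(ang)
    L = spec.avf_path_length
    rmax = max(spec.vein.max_diameter, spec.fistula.nominal_diameter) / 2.0
    xs = [-spec.proximal_artery.length, spec.distal_artery.length, 0.0, L * ux]
    ys = [0.0, L * uy]
    pad = rmax + margin_voxels * sp
    lo = np.array([min(xs) - pad, min(ys) - pad, -pad])
    hi = np.array([max(xs) + pad, max(ys) + pad, pad])
    shape = np.maximum(np.ceil((hi - lo) / sp).astype(int) + 1, 2)
    ax = [lo[a] + sp * np.arange(shape[a]) for a in range(3)]
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    inside = _lumen_distance_test(spec, x, y, z)
    values = np.where(inside, hu_vessel, hu_background).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return VoxelVolume(values=values, spacing_um=spacing_um, origin_mm=tuple(lo))


def phantom_landmarks(spec: GeometrySpec, volume: VoxelVolume) -> dict[str, tuple[int, int, int]]:
    """Voxel indices of labeled endpoint seeds (PA, DA, vein ends + anastomosis).

    Endpoints sit one lumen-radius inside each open end so they are robust
    to endcap voxelization.
    """
    sp = volume.spacing_mm
    lo = np.array(volume.origin_mm)
    ang = np.deg2rad(spec.anastomosis_angle)
    u = np.array([np.cos(ang), np.sin(ang), 0.0])
    pts = {
        "PA": np.array([-spec.proximal_artery.length + 2 * sp, 0.0, 0.0]),
        "DA": np.array([spec.distal_artery.length - 2 * sp, 0.0, 0.0]),
        "vein": (spec.avf_path_length - 2 * sp) * u,
        "anastomosis": np.zeros(3),
    }
    out = {}
    for k, p in pts.items():
        idx = np.round((p - lo) / sp).astype(int)
        idx = np.clip(idx, 0, np.array(volume.values.shape) - 1)
        out[k] = tuple(int(i) for i in idx)
    return out


# --------------------------------------------------------------------------
# pulsatile waveforms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic waveform sampled over one or more cardiac cycles.

    ``period_s`` is the cardiac period (60/heart-rate); ``times`` may span
    several periods for raw multi-cycle records.  Evaluation wraps
    periodically with linear interpolation.
    """

    period_s: float
    times: np.ndarray  # s, strictly increasing, starting at 0
    values: np.ndarray  # mm/s for velocity kinds, mL/min for flow_rate
    kind: Literal["peak_velocity", "mean_velocity", "flow_rate"]
    heart_rate_bpm: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        _require(t.ndim == 1 and t.size >= 2, "waveform needs at least two samples")
        _require(np.all(np.diff(t) > 0), "sample times must be strictly increasing")
        _require(np.all(np.isfinite(v)), "waveform values must be finite")
        _require(
            abs(self.period_s - 60.0 / self.heart_rate_bpm) < 1e-9,
            "period must equal 60/heart_rate",
        )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n_cycles(self) -> float:
        return (self.times[-1] - self.times[0]) / self.period_s

    def __call__(self, t):
        """Periodic linear interpolation (single-cycle waveforms only)."""
        tt = np.mod(np.asarray(t, float), self.period_s)
        tp = np.concatenate([self.times, [self.times[0] + self.period_s]])
        vp = np.concatenate([self.values, [self.values[0]]])
        out = np.interp(tt, tp, vp)
        return out if out.ndim else float(out)

    def scaled(self, factor: float, kind=None) -> "FlowWaveform":
        return FlowWaveform(
            period_s=self.period_s,
            times=self.times.copy(),
            values=self.values * factor,
            kind=kind or self.kind,
            heart_rate_bpm=self.heart_rate_bpm,
        )


def synth_waveform(
    peak_velocity: float,
    heart_rate: float = 450.0,
    pulsatility: float = 0.5,
    n_harmonics: int = 6,
    n_samples: int = 200,
    seed: int = 0,
) -> FlowWaveform:
    """Synthesize a Doppler-like periodic peak-velocity waveform.

    The shape is a systolic bump (von-Mises-like) truncated to
    ``n_harmonics`` Fourier modes with small seed-deterministic amplitude
    jitter, rescaled so the sampled maximum equals ``peak_velocity``
    exactly and the minimum equals ``(1 - pulsatility) * peak_velocity``.
    ``pulsatility >= 1`` would produce flow reversal at the artery inlet
    and is rejected.
    """
    _require(peak_velocity > 0, "peak_velocity must be > 0")
    _require(heart_rate > 0, "heart_rate must be > 0")
    if not 0.0 <= pulsatility < 1.0:
        raise ValidationError(
            f"pulsatility must be in [0, 1) (>= 1 reverses the inlet), got {pulsatility}"
        )
    period = 60.0 / heart_rate
    t = np.linspace(0.0, period, n_samples, endpoint=False)
    if pulsatility == 0.0:
        v = np.full(n_samples, peak_velocity)
        return FlowWaveform(period, t, v, "peak_velocity", heart_rate)
    phase = 2 * np.pi * t / period
    kappa = 3.0  # systolic bump concentration
    bump = np.exp(kappa * (np.cos(phase - 2 * np.pi * 0.2) - 1.0))
    coeff = np.fft.rfft(bump)
    coeff[n_harmonics + 1 :] = 0.0
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.05 * rng.standard_normal(min(n_harmonics, coeff.size - 1))
    coeff[1 : 1 + jitter.size] *= jitter
    shape = np.fft.irfft(coeff, n=n_samples)
    shape = (shape - shape.min()) / (shape.max() - shape.min())  # exactly [0, 1]
    v = peak_velocity * ((1.0 - pulsatility) + pulsatility * shape)
    return FlowWaveform(period, t, v, "peak_velocity", heart_rate)


def record_cycles(
    waveform: FlowWaveform,
    n_cycles: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FlowWaveform:
    """Concatenate ``n_cycles`` repeats of a single-cycle waveform with
    optional additive Gaussian noise — a stand-in for a raw multi-cycle
    Doppler trace."""
    _require(n_cycles >= 1, "n_cycles must be >= 1")
    T = waveform.period_s
    ts = np.concatenate([waveform.times + k * T for k in range(n_cycles)])
    vs = np.tile(waveform.values, n_cycles)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vs = vs + rng.normal(0.0, noise_sd, size=vs.size)
    return FlowWaveform(T, ts, vs, waveform.kind, waveform.heart_rate_bpm)
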