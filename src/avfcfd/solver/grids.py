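"""Structured staggered (MAC) grids for the desk-scale solvers.

Two topologies replace the study's 3-D tetrahedral meshes:

* an **axisymmetric tube** following the fistula-path radius law r(s)
  through a body-fitted mapping eta = r / R(z) onto a rectangle — this
  carries the stenosis physics (pressure drop, TAWSS/OSI profiles), and
* a **planar T-junction** of axis-aligned channels on a masked Cartesian
  grid — this carries the junction/flow-split physics.

Three named resolution levels refine by 2x per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..synth import GeometrySpec, ValidationError

__all__ = ["TubeGrid", "JunctionGrid", "build_grid", "LEVELS"]

#: transverse cells across the radius per level (axial density scales with it)
LEVELS = {"coarse": 8, "medium": 16, "fine": 32}

#: axial cells per mm at the coarse level (tube topology)
_NZ_PER_MM_COARSE = 8


@dataclass(frozen=True)
class TubeGrid:
    """Body-fitted axisymmetric tube grid.

    Computational coordinates: xi = z in [s0, s1] (m), eta = r/R(z) in
    [0, 1].  u (axial velocity) lives on xi-faces x eta-centers, v (radial)
    on xi-centers x eta-faces, pressure on cell centers.  Boundary tags:
    ``inlet`` (xi = s0), ``outlet`` (xi = s1), ``wall`` (eta = 1) and the
    symmetry ``axis`` (eta = 0).
    """

    s0_m: float
    s1_m: float
    nz: int
    nr: int
    level: str
    R_face: np.ndarray  # (nz+1,) wall radius at xi-faces, m
    Rp_face: np.ndarray  # dR/dz at xi-faces
    Rpp_face: np.ndarray
    R_cell: np.ndarray  # (nz,) at xi-centers
    Rp_cell: np.ndarray
    Rpp_cell: np.ndarray

    @property
    def dxi(self) -> float:
        return (self.s1_m - self.s0_m) / self.nz

    @property
    def deta(self) -> float:
        return 1.0 / self.nr

    @property
    def xi_face(self) -> np.ndarray:
        return self.s0_m + self.dxi * np.arange(self.nz + 1)

    @property
    def xi_cell(self) -> np.ndarray:
        return self.s0_m + self.dxi * (np.arange(self.nz) + 0.5)

    @property
    def eta_face(self) -> np.ndarray:
        return self.deta * np.arange(self.nr + 1)

    @property
    def eta_cell(self) -> np.ndarray:
        return self.deta * (np.arange(self.nr) + 0.5)

    @property
    def near_wall_spacing_m(self) -> float:
        return float(self.deta * self.R_face.min())

    def cell_volumes(self) -> np.ndarray:
        """Cell volumes per unit azimuthal radian, (nz, nr)."""
        eta = self.eta_cell
        return self.dxi * self.deta * eta[None, :] * self.R_cell[:, None] ** 2

    def r_of_cells(self) -> np.ndarray:
        """Physical radius r (m) at cell centers, (nz, nr)."""
        return self.eta_cell[None, :] * self.R_cell[:, None]

    def min_transverse_cells(self) -> int:
        # body-fitted: the full diameter is always spanned by 2*nr cells
        return 2 * self.nr


@dataclass(frozen=True)
class JunctionGrid:
    """Masked Cartesian grid of a planar T-junction.

    The artery runs along x (width = PA diameter, centred on y = 0); the
    fistula/vein channel leaves the artery's far wall at x = 0 and runs to
    the top boundary.  Open boundaries: ``inlet_PA`` (x = xmin),
    ``outlet_DA`` (x = xmax), ``outlet_vein`` (y = ymax over the fistula
    channel); every other fluid-facing boundary is a no-slip wall.
    """

    h: float  # isotropic cell size, m
    x0: float
    y0: float
    fluid: np.ndarray  # (nx, ny) bool cell mask
    level: str
    artery_halfwidth: float  # m
    fistula_halfwidth: float
    vein_cols: tuple[int, int]  # column range [lo, hi) of the vein outlet

    @property
    def nx(self) -> int:
        return self.fluid.shape[0]

    @property
    def ny(self) -> int:
        return self.fluid.shape[1]

    @property
    def x_cell(self) -> np.ndarray:
        return self.x0 + self.h * (np.arange(self.nx) + 0.5)

    @property
    def y_cell(self) -> np.ndarray:
        return self.y0 + self.h * (np.arange(self.ny) + 0.5)

    def open_boundaries(self) -> list[str]:
        return ["inlet_PA", "outlet_DA", "outlet_vein"]


def _radius_derivatives(spec: GeometrySpec, s_m: np.ndarray):
    r = spec.avf_radius_m()
    h = 2e-6  # m; radius law is smooth at this scale
    R = r(s_m)
    Rp = (r(s_m + h) - r(s_m - h)) / (2 * h)
    Rpp = (r(s_m + h) - 2 * R + r(s_m - h)) / h**2
    return R, Rp, Rpp


def build_tube_grid(spec: GeometrySpec, level: str = "coarse") -> TubeGrid:
    """Axisymmetric grid over the fistula path: the straight inlet
    extension, the fistula (with stenosis), and the vein."""
    if level not in LEVELS:
        raise ValidationError(f"unknown resolution level {level!r}")
    refine = LEVELS[level] // LEVELS["coarse"]
    nr = LEVELS[level]
    s0 = -spec.inlet_extension * 1e-3
    s1 = spec.avf_path_length * 1e-3
    L_mm = (s1 - s0) * 1e3
    nz = int(round(L_mm * _NZ_PER_MM_COARSE)) * refine
    if 2 * nr < 8:
        raise ValidationError(
            f"level {level!r} resolves the minimum lumen with fewer than 8 cells"
        )
    dxi = (s1 - s0) / nz
    xi_f = s0 + dxi * np.arange(nz + 1)
    xi_c = s0 + dxi * (np.arange(nz) + 0.5)
    Rf, Rpf, Rppf = _radius_derivatives(spec, xi_f)
    Rc, Rpc, Rppc = _radius_derivatives(spec, xi_c)
    return TubeGrid(
        s0_m=s0, s1_m=s1, nz=nz, nr=nr, level=level,
        R_face=Rf, Rp_face=Rpf, Rpp_face=Rppf,
        R_cell=Rc, Rp_cell=Rpc, Rpp_cell=Rppc,
    )


def straight_tube_grid(radius_m: float, length_m: float, nz: int, nr: int,
                       level: str = "custom") -> TubeGrid:
    """Uniform straight tube (validation cases: Poiseuille, pulsatile
    fully-developed flow)."""
    z = np.zeros
    return TubeGrid(
        s0_m=0.0, s1_m=length_m, nz=nz, nr=nr, level=level,
        R_face=np.full(nz + 1, radius_m), Rp_face=z(nz + 1), Rpp_face=z(nz + 1),
        R_cell=np.full(nz, radius_m), Rp_cell=z(nz), Rpp_cell=z(nz),
    )


def build_junction_grid(spec: GeometrySpec, level: str = "coarse") -> JunctionGrid:
    """Planar T-junction grid: artery channel along x, fistula channel up."""
    if level not in LEVELS:
        raise ValidationError(f"unknown resolution level {level!r}")
    n_across = LEVELS[level]  # cells across the artery width
    wa = spec.proximal_artery.diameter * 1e-3
    wf = spec.fistula.nominal_diameter * 1e-3
    h = wa / n_across
    # short limbs: at junction Reynolds numbers the development length is a
    # fraction of a diameter, so ~1 mm per limb isolates the junction physics
    La = 1.2e-3  # artery limb length per side, m
    Lf = 1.5e-3  # fistula channel height, m
    x0 = -La - wf / 2
    x1 = La + wf / 2
    y0 = -wa / 2
    y1 = wa / 2 + Lf
    nx = int(round((x1 - x0) / h))
    ny = int(round((y1 - y0) / h))
    xc = x0 + h * (np.arange(nx) + 0.5)
    yc = y0 + h * (np.arange(ny) + 0.5)
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    in_artery = np.abs(Y) <= wa / 2
    in_fistula = (np.abs(X) <= wf / 2) & (Y >= 0)
    fluid = in_artery | in_fistula
    cols = np.flatnonzero(fluid[:, -1])
    if cols.size == 0:
        raise ValidationError("fistula channel does not reach the top boundary")
    if fluid[:, -1].sum() * h < 8 * h:
        raise ValidationError("fewer than 8 cells across the fistula channel")
    return JunctionGrid(
        h=h, x0=x0, y0=y0, fluid=fluid, level=level,
        artery_halfwidth=wa / 2, fistula_halfwidth=wf / 2,
        vein_cols=(int(cols[0]), int(cols[-1] + 1)),
    )


def build_grid(spec: GeometrySpec, level: str = "coarse",
               topology: str = "axisymmetric_tube"):
    """Dispatch on topology: ``axisymmetric_tube`` or ``planar_junction``."""
    if topology == "axisymmetric_tube":
        return build_tube_grid(spec, level)
    if topology == "planar_junction":
        return build_junction_grid(spec, level)
    raise ValidationError(f"unknown topology {topology!r}")
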