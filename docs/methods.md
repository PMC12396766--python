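# Methods

This package re-creates, at desk scale and on synthetic data, the analysis
chain used to characterize hemodynamics in a maturing murine arteriovenous
fistula (AVF): contrast micro-CT-like imaging of the lumen, segmentation
and centerline diameter profiling, Doppler-style pulsatile boundary
conditions, an incompressible Navier–Stokes simulation over cardiac
cycles, and the standard wall-shear metrics. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
setting can and cannot show.

## Geometric model and phantoms

The vascular network is parametric (`synth.GeometrySpec`): a straight
carotid-like artery (proximal and distal limbs), an end-to-side
fistula/vein path leaving the artery at a configurable angle (default
90°), a Gaussian stenosis of the fistula radius, and a logistic
"ballooning" of the vein capped smoothly at its maximal diameter. All
lengths are millimetres at the interface; everything internal is SI.

The `day7` and `day21` presets encode the published per-segment lumen
statistics of the study system (artery diameters; mean/min/max over the
first 2 mm and 4 mm of the fistula; vein maximum). Because only window
statistics are published, the free shape parameters of the analytic
diameter law — base level, logistic midpoint/width/asymptote, stenosis
center and width — are calibrated once, at preset construction, by least
squares against those statistics (residuals < 0.005 mm, enforced). The
stenosis center/width search is bounded so the early lesion is short and
anastomosis-adjacent and the late lesion elongated and shifted
downstream, matching the described remodelling. The throat diameter is
reproduced exactly by construction. The stenosis standard deviation is
`width/3`, so the lumen recovers to ~1% of nominal one `width` from the
center.

Two diameter-law details exist purely for numerical hygiene: the vein cap
is a soft minimum (0.02 mm width) and the straight inlet extension joins
at `s = 0` through a 0.1 mm soft hinge, keeping the radius law C¹ — the
solver's body-fitted mapping differentiates it twice.

The voxelizer marks voxels whose centers lie inside the lumen union
(artery tube ∪ fistula tube; the junction is the plain union, with no
fillet — a fillet radius would be a free parameter nothing downstream
could validate). Default spacing is the scanner's 72 µm isotropic;
contrast lumen is 650 HU on a 0 HU background with optional Gaussian
noise (seeded). Scanner physics (beam hardening, contrast kinetics) is
not emulated.

Waveforms: a von-Mises-like systolic bump truncated to `n_harmonics`
Fourier modes with small seeded amplitude jitter, rescaled so the sampled
maximum equals the requested peak exactly and the minimum equals
`(1 - pulsatility) * peak`. Defaults: 450 bpm (period 133 ms) and
pulsatility 0.5, a typical murine carotid pulsatility index; `pulsatility
>= 1` is rejected because the model does not support inlet flow reversal.
Flow scale is set by the measured AVF flow (time-averaged 1.33 mL/min at
day 7, 2.57 mL/min at day 21) with flow splits of 80/20 and 70/30 between
fistula and distal artery.

## Imaging chain

Segmentation is the interactive-tool chain made reproducible: an
inclusive 300–1000 HU window (bone-like objects survive), then seeded
region growing (default 26-connectivity) that keeps only components
containing a seed. Surfaces come from marching cubes at level 0.5 on a
Gaussian-anti-aliased indicator (σ = 0.8 voxels; raw binary contouring
overestimates areas by ~10% through staircase facets), and smoothing is
Taubin's volume-preserving scheme — plain Laplacian smoothing shrinks the
lumen and would bias exactly the comparative diameter statistics this
pipeline exists to produce. A > 2% volume change during smoothing is an
error, not a warning.

## Centerlines and diameter profiles

Centerlines are distance-transform-weighted shortest paths (cost ∝
inverse squared wall distance, so paths ride the medial ridge) traced
between labeled endpoints with sub-voxel smoothing and uniform arc-length
resampling (default 0.05 mm). Arc length is zero at the anastomosis,
negative along both artery limbs, positive along the fistula/vein.

The anastomosis landmark needs care: near a T-junction, *every* medial
path bulges into the junction mouth (wall distance is largest there), so
the raw divergence point of the two vein-bound paths sits a few voxels up
the fistula. `s = 0` is therefore defined as the intersection of the
fistula path's initial direction with the artery axis fitted away from
the junction; without this re-basing the arc-length offset (~0.26 mm on
the day-7 phantom) aliases into a several-voxel apparent diameter error
wherever the radius law is steep.

Cross-sections are sampled on planes normal to the local tangent
(trilinear lumen interpolation at half-voxel pitch), restricted to the
in-plane connected region containing the centerline point, and reported
as equivalent diameter `2·sqrt(A/π)` — sections near the anastomosis are
not circular, and sections within about half the fistula-mouth diameter
of `s = 0` (0.5 mm default) are excluded from segment statistics because
no single-vessel cross-section exists there. On noise-free phantoms the
full voxelize → segment → profile chain recovers the analytic diameter
law within one voxel spacing outside that exclusion zone (this is a
tested invariant).

A consequence worth stating: the published 2-mm-window statistics cover
[0, 2] mm including the junction-adjacent region. Over the measurable
[0.5, 2] mm window the preset laws themselves give a day-7 → day-21 mean
change of −33% rather than the tabulated −21.6% (the late timepoint's
expanded anastomosis region falls inside the excluded zone), and the
measured comparison reproduces that windowed value — so the comparison
report is validated against the analytic law on the same window, while
the tabulated percent changes are recomputed exactly from the published
diameters themselves.

Poiseuille resistance integrates `8μ/(π r⁴)` along the profile
(trapezoid); it is the basis of the day-21/day-7 resistance-ratio
comparison.

## Boundary conditions

Doppler emulation: multi-cycle records are phase-aligned by circular
cross-correlation against the first cycle and averaged over three
consecutive cycles. Peak velocity converts to mean velocity by the
parabolic-profile factor 2 (axisymmetric), justified by the Womersley
number α = R√(ωρ/μ) ≈ 1 at these scales (0.29 mm radius, 450 bpm, ρ =
1040 kg/m³, μ = 4×10⁻³ Pa·s); flow is Q = A·V. Inlets are time-varying
parabolas whose disk integral equals Q(t) identically; the planar solver
applies the 3/2 channel factor internally.

## Solver

The study's 3-D tetrahedral finite-volume simulations are replaced by two
structured reductions that keep every reported quantity exercisable:

* **Axisymmetric tube** for the stenosis physics (pressure drop, TAWSS,
  OSI, velocity/pressure profiles): the fistula-path radius law r(s) is
  body-fitted by η = r/R(z) onto a rectangle. Variables are MAC-staggered;
  the mapped operators carry the full metric terms (cross-derivatives,
  1/r terms, azimuthal strain).
* **Planar T-junction** on a masked Cartesian grid for the flow-split and
  junction-vortex physics, with prescribed parabolic inflow (proximal
  artery), prescribed parabolic *outflow* on the distal artery carrying
  the configured split fraction, and a zero-pressure venous outlet.

Absolute 3-D values are out of scope by design; comparisons are within
and between the two reductions.

Time discretization is backward Euler with Picard outer iterations: each
iteration solves an implicit-diffusion momentum predictor (second-order
upwind convection evaluated at the previous iterate, first-order fallback
in the one-cell boundary band) followed by an incremental
pressure-correction projection. The projection operator is assembled as
the exact sparse composition of the discrete divergence (conservative
contravariant fluxes of the mapping) with the through-face pressure
gradient, so post-step cell divergence is at direct-solver precision
(≲10⁻¹² s⁻¹, asserted ≤ 10⁻⁸ per cell). Momentum uses the full mapped
pressure gradient; the split converges to the coupled backward-Euler
solution because the Picard loop iterates predictor and projection
together until the normalized inter-iterate residual falls below 10⁻⁶
(L∞ per equation; iteration caps raise a solver error with the residual
trace). With a second-order extrapolated initial guess, 2–4 iterations
per step are typical.

The advective CFL number is capped at 0.1, as in the study protocol, by
adapting the time step on a halving ladder (factor-2 steps so momentum
factorizations are cached per Δt); a step whose *post-step* CFL exceeds
the cap is rejected and retried with half the step, since pre-step fields
underestimate the rate during transients. Runs start from rest, last
three cardiac cycles, and store 200 uniform phase snapshots of the final
cycle; an inlet-pressure trace per cycle feeds the periodicity check
(relative L2 between consecutive cycles; the first cycle absorbs the
impulsive start and the third is analysis-grade, deviations ~10⁻⁶).

Wall treatment: no-slip enters the u-momentum Laplacian through a
quadratic ghost fitted through the wall zero and two interior points.
This makes the parabolic profile an exact discrete solution — steady
Poiseuille flow is reproduced to solver precision at any resolution, and
wall shear stress is second-order accurate. A graded near-wall mesh was
considered and rejected: the η-mapping already concentrates physical
resolution at the stenosis throat, and uniform η keeps every operator row
constant-coefficient.

Resolution levels: coarse = 8 cells across the radius and 8 axial cells
per mm, refined 2× per axis per level (medium, fine). Coarse satisfies
the ≥ 8-cells-across-minimum-lumen contract with margin (the body-fitted
map always spans the diameter with 2·nr cells). The day-7 pulsatile
three-level study runs in ~7 minutes on one CPU (fine level ~6 min);
these sizes are the package's standard study configuration.

Validation (all tested): Poiseuille profile/WSS/pressure drop (exact /
< 1%), the pulsatile Womersley solution at α ≈ 1 within 3% L∞ (measured
~0.1% at the validation resolution), exact mass conservation (discrete
telescoping of divergence-free cells), pressure gauge invariance under
the zero-pressure outlet, linearity of the pressure drop in μ, and
time-step-halving invariance within 0.5%.

### Grid-convergence study

Three refinements of the pulsatile day-7 stenotic tube are compared at
peak systole on the common coarse-level station set; the report is the
max-norm relative difference of velocity magnitude and pressure
(normalized by the finer member's peak) plus the observed order. Field
values at common stations are evaluated with *cubic* interpolants: linear
interpolation of the medium field contributes its own O(h²) error with a
large constant in the stenotic jet's shear layer, which masks the
solution difference the study is meant to measure (with linear
evaluation the apparent order drops to ~0.8; with cubic it is ~1.9,
matching the scheme's formal order). Medium-vs-fine differences are
below 1% for both fields, the same criterion the full-scale study used
to accept its medium mesh.

## Hemodynamic metrics

* WSS: signed wall-tangential traction μ·∂u_t/∂n from a one-sided
  quadratic fit through the wall and the two nearest interior stations,
  measured along the wall normal (validated against 4μQ/πR³ to < 1%).
* TAWSS: trapezoid time average of |τ| over the stored final cycle,
  closed periodically. OSI = ½(1 − |∫τ dt|/∫|τ| dt) ∈ [0, 0.5]; the WSS
  "vector" in these reductions is the signed tangential component, and
  identically zero shear is assigned OSI = 0 (the definition is 0/0
  there). Steady runs are treated as constant over a notional cycle
  (TAWSS = |τ|, OSI = 0).
* Q-criterion: ½(‖Ω‖² − ‖S‖²) from staggered-exact diagonal gradients and
  centered cross-gradients; the axisymmetric rate-of-strain includes the
  azimuthal term v/r.
* Profiles: per-station cross-sectional maximum and area-weighted average
  (weights ∝ η for the mapped annulus); windowed averages over the first
  4 mm use trapezoid integration in arc length.
* Flow splits are time-averaged boundary fluxes normalized by the inlet
  flux; an imbalance above 0.5% raises (it would mean the projection
  failed). Pressure-drop localization is the fraction of the total
  centerline pressure drop within a given distance of the anastomosis;
  values above 1 are physical (Bernoulli pressure recovery downstream of
  the stenotic jet). The TAWSS–diameter relation is a log-log linear fit
  (exponent −3 for Poiseuille flow at constant flow rate; recovered to
  ±0.01 on synthetic data, and negative on all stenotic solver runs).

## What the synthetic setting shows — and does not

Passing tests demonstrate that every operator in the chain is correct
against analytic oracles and that the qualitative temporal signature of
stenosis development is reproduced end to end on the presets: a several-
fold rise of the 4-mm-averaged TAWSS (measured ~6× on the coarse runs,
2.0 → 11.7 Pa), the appearance of a broad elevated-OSI region downstream
of the elongated late stenosis (absent on day 7), a Poiseuille resistance
ratio well above 1, a more localized pressure drop, and peak velocities
shifting into the stenotic segment. The study's absolute murine values
(TAWSS peaks of order 10² Pa, specific OSI maxima, 99%-vs-50% drop
localization, the ~9× resistance ratio) depend on the real, non-deposited
animal geometries and ultrasound traces; phantoms are not expected to
reproduce them and no test asserts them. Real data additionally contain
partial-volume and contrast heterogeneity, wall motion, and Doppler angle
error, none of which the generator emulates.

## Degenerate inputs and tie-breaks

Empty threshold windows, background seeds, border-touching masks,
non-watertight smoothing inputs, disconnected centerline endpoints,
empty profile windows, non-positive radii, single-phase time integrals
(except steady fields), reversing inlets, and split fractions outside
[0, 1) all raise `ValidationError` naming the offending quantity. The
peak-systole phase is the stored snapshot of maximum inlet flow;
tie-breaks take the first index. Seeds thread from one config value
through every stochastic stage (phantom noise, waveform jitter, record
noise); all solver stages are deterministic.
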