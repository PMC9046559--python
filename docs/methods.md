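# Methods

`hemoflow` simulates pulsatile blood flow in two-dimensional models of
coronary vessels and quantifies how the choice of blood rheology — constant
("Newtonian") viscosity versus the shear-thinning Quemada suspension law —
changes the wall-based hemodynamic indices used in atherosclerosis research.
This note records the models, the numerical choices, the parameters that
matter, and what the synthetic inputs do and do not establish.

## Flow model

Incompressible Navier–Stokes with variable dynamic viscosity
μ(γ̇), solved in two geometric idealizations of a coronary segment:

- **planar**: a symmetric 2D channel of local height D(x); the half-domain
  between the centerline and the wall is solved with a symmetry condition.
  This is the mode used for the idealized stenotic-artery experiment.
- **axisymmetric**: a rigid tube in (x, r); used for validation against the
  Poiseuille and Womersley closed forms and for the synthetic vessel cohort.

Boundary conditions: time-varying parabolic inlet velocity carrying the
prescribed flow waveform; rigid no-slip wall; symmetry at the
centerline/axis; a single outlet with a linear resistance p = R·Q (default
R = 0, i.e. a reference pressure — with one outlet the resistance only
shifts the absolute pressure level, not the flow). Simulations start from
rest and run `n_cycles` (default 3) cardiac cycles; only the final cycle is
stored, at 64 evenly spaced instants. Convergence to a periodic state is
measured, not assumed: the relative L2 distance between the wall-shear
series of the last two cycles is reported as `cycle_periodicity` (observed
~1e-12 for the default cases, because the prescribed-inflow problem locks
onto its periodic orbit within a cycle).

### Flow-rate convention in the planar mode

A volumetric waveform Q(t) (m³/s) must be mapped onto a 2D model. The
package converts it **per unit depth**: the channel of height D carries the
2D flow rate q(t) = Q(t)/D, i.e. bulk velocity U = Q/D². (The alternative —
the circular-equivalent-area bulk velocity U = Q/(πD²/4) — is exactly π/4⁻¹
times larger.) The per-depth convention reproduces the reported idealized
straight-segment shear stress of the baseline study to −2.5%, and is the
natural normalization for a 2D finite-volume model; it is therefore the
planar default. The axisymmetric mode integrates Q(t) over the tube section
exactly.

### Idealized stenosis geometry

D(x) = D_min + (D − D_min)·sin²(πx/L) for |x| ≤ L/2, with D = 3 mm,
L = 3 mm, and x = 0 at the minimum lumen diameter; straight vessel
elsewhere (5 D upstream, 10 D downstream by default). The printed source
form of this equation is dimensionally inconsistent (a global ½ factor and
a dimensional sine argument); the implemented form satisfies the stated
anchors: minimum at x = 0, reference diameter at the shoulders, C¹ across
them.

Two readings of "40% diameter stenosis" are supported: `paper_literal`
(D_min = DS·D = 1.2 mm) and `clinical` (D_min = (1−DS)·D = 1.8 mm). The
**pipeline default is clinical**: simulated with the literal throat, the
idealized artery produces ~12 Pa throat shear and a segment-2 median far
above the straight-segment value, contradicting the published baseline
table, whereas the clinical throat reproduces every feature of it
(segment-2 median equal to the straight value, low segment-3 median, small
IQRs in the healthy segments). `StenosisSpec` itself defaults to
`paper_literal` so the constructor follows the verbal definition.

The wall is partitioned into four segments: (1) proximal vessel ending one
diameter before the proximal shoulder, (2) one diameter before the shoulder
through the MLD (closed-left: the MLD station is in segment 2), (3) MLD to
one diameter past the distal shoulder, (4) the remaining distal vessel.

## Rheology

Newtonian: μ = 3.5 mPa·s (ρ = 1060 kg/m³, haematocrit 45% throughout).

Quemada: μ(γ̇) = μ_p (1 − k(γ̇)H/2)⁻², k = (k0 + k∞√(γ̇/γ_c))/(1 + √(γ̇/γ_c)),
evaluated at max(γ̇, γ_floor) with γ_floor = 10⁻³ s⁻¹ to avoid the
zero-shear blow-up on discrete fields. Viscosity is re-evaluated each time
step from the instantaneous local shear-rate invariant γ̇ = √(2 D:D) — no
thixotropic history.

Two named parameter sets:

| set | μ_p (Pa·s) | k0 | k∞ | γ_c (1/s) | use |
|---|---|---|---|---|---|
| `literature_params` | 0.0012 | 4.33 | 2.07 | 1.88 | standard H = 0.45 whole-blood fit |
| `calibrated_params` | 0.0012 | 4.33 | 2.07 | **0.0458** | idealized pipeline & acceptance |

The baseline study did not publish its Quemada parameterization. γ_c in
`calibrated_params` is fitted (one scalar, by an independent 1-D
fully-developed-channel oracle, before any solver run) so that the
fully developed planar Newtonian→Quemada wall-shear ratio at the idealized
operating point equals the reported healthy-segment ratio 0.8238/0.6618.
Two independent consistency checks fall out rather than being fitted: the
implied peak local-blood-viscosity ratio at the shear floor is 41.2-fold
(the reported average peak is 41.5-fold, versus 517-fold implied by the
literature γ_c), and the high-shear plateau μ_p(1 − k∞H/2)⁻² = 4.20 mPa·s
is reached to 0.1% by γ̇ = 10⁶ s⁻¹.

LBV (local blood viscosity) = μ_local/μ_Newtonian; 1 means no
non-Newtonian effect. Because the Quemada plateau (4.20 mPa·s) exceeds
3.5 mPa·s, LBV > 1 everywhere — the Quemada model predicts uniformly
higher viscous stresses, which is why it raises ESS in every segment.

## Numerics

Body-fitted mapped grid: x uniform; η = y/r(x) ∈ [0,1] transverse with a
geometrically stretched near-wall block (default 10 layers, ratio 1.25,
innermost layer matched to the core spacing). Staggered arrangement in
computational space (u at x-faces, v at η-faces, p at centers); metric
terms from the analytic radius function.

Time stepping is a first-order semi-implicit fractional step:

- advection: explicit, third-order upwind-biased in x, nonuniform central
  in η, on the mapped advecting velocities (u, η̇); stabilized by folding
  first-order upwind advection *of the increment* into the implicit solve
  (deferred correction — the steady state retains the higher-order scheme).
  First-order upwinding of the advection term itself was tried first and
  rejected: its numerical viscosity (~9× molecular at the throat)
  suppressed the post-stenotic recirculation entirely.
- diffusion: the full variable-viscosity stress divergence is explicit;
  the grid-aligned principal part is additionally solved implicitly by a
  Douglas–Gunn ADI factorization (tridiagonal sweeps), removing the
  near-wall and high-viscosity (Quemada low-shear) time-step limits.
- pressure: incremental projection. The projection operator is assembled
  **exactly** as the sparse product of the discrete divergence and
  correction-gradient operators (including all metric cross-terms and the
  mapped-flux coupling) and LU-factorized once; a single solve per
  iteration makes the corrected field divergence-free to factorization
  precision (observed ~1e-12). A compact 5-point approximation was tried
  first and stalled (contraction factor ≈ 0.99 near the sloped wall).

The time step is CFL-derived (target 0.7 on a conservative peak-velocity
estimate) and snapped so an integer number of steps lands on each of the
64 output instants. Mass conservation (inlet vs outlet flux) holds to
~1e-15 relative at every stored instant.

Validation: steady Poiseuille tube wall shear within 0.25% of
32μQ/(πD³); single-harmonic pulsatile wall shear within 0.2% L2 of the
analytic rigid-tube (Womersley) series; grid-refinement change of probe
wall shear < 2% on the default case.

## Indices

ESS is the signed tangential viscous traction μ_w ∂u_t/∂n at the wall,
evaluated by a one-sided quadratic fit through the two near-wall cell rows
and the no-slip wall (exact for parabolic profiles); for Quemada runs μ_w
is the constitutive viscosity at the wall shear rate. Time integrals over
the stored cycle use uniform periodic sampling (rectangle = periodic
trapezoid), making cycle averages of pure harmonics exact.

- time-averaged ESS: cycle mean of |ESS| per wall point.
- ESSG: |∂ESS/∂s| along the wall arc length (nonuniform 3-point central
  differences, one-sided at the ends), reported in Pa/mm. In this 2D
  reduction the surface-tensor "diagonal magnitude" collapses to the single
  along-wall derivative.
- OSI = 0.5(1 − |∮ESS dt|/∮|ESS| dt) ∈ [0, 0.5]; stagnant points are
  defined as 0.
- normalized ESS: |ESS| scaled by each point's cycle maximum (∈ [0,1]).
- low-ESS area: area-weighted percent of wall with time-averaged ESS below
  1 Pa (axisymmetric weights 2πr ds; planar ds per unit depth). The
  time-averaged definition is used; an instantaneous variant can be built
  from the stored series.
- LBV summary: volume-weighted mean LBV (time-averaged) and the global
  peak with its snapshot; `peak_lbv_nadir_distance` measures the cyclic
  time distance from the peak-LBV snapshot to the nearest local minimum of
  the inflow waveform.

Per-segment summaries are medians and IQRs over wall points
(linear-interpolation quartiles), matching how the baseline reports them.

## Statistics

Two rheology runs share one grid, so comparisons are paired point-by-point.
`paired_compare` auto-selects a paired t-test when a Shapiro–Wilk screen of
the differences (α = 0.05, capped at 5000 points) does not reject
normality, else the Wilcoxon signed-rank test; two-tailed at α = 0.05, no
multiplicity adjustment. `bootstrap_pointwise` decorrelates the spatially
dependent mesh data by drawing 1.5% of points with replacement 10,000 times
(both configurable) and reports the percentile 95% CI of the median
difference (mean available); percentile rather than BCa for transparency.
Simulated coverage of a known shift is 93–94% over 200 repetitions, and the
raw-data statistic always lies inside the CI on the packaged examples.

## Synthetic inputs

- **Waveform**: baseline plus one raised-sine lobe per phase — systole
  (fraction 0.44 of the 0.8 s cycle) and diastole with dominance ratio 2.0
  and baseline 0.4 — scaled analytically so the cycle mean is exact. C¹,
  strictly positive, flow nadirs at t = 0 and at the systole/diastole
  transition (0.352 s), peak in early-mid diastole. The dominance and
  baseline values are a choice of typical left-coronary morphology, not a
  fit; all shape parameters are exposed.
- **Synthetic vessels**: axisymmetric tubes (radius 1.5 mm, length 13.4 mm,
  the cohort's region-of-interest scale) with seeded random-Fourier lumen
  perturbations (10% relative amplitude, ~4 mm correlation length), seeds
  1–16; per-vessel mean flows are seeded draws from Normal(0.83, 0.44) mL/s
  truncated at 0.2. They emulate the smooth caliber variation of
  imaging-derived lumens but not eccentricity, curvature, bifurcations or
  plaque geometry — so cohort-level tests establish the *direction* of
  rheology effects across realistic flow/caliber ranges, not patient-level
  magnitudes.
- **Analytic fixtures**: exact Poiseuille fields and the rigid-tube
  pulsatile (Womersley) wall-shear series, implemented independently of the
  solver as oracles.

## Known limitations

- 2D planar/axisymmetric only; no secondary flow, curvature, bifurcations
  or patient-specific 3D lumens. Rigid walls; no fluid–structure
  interaction; laminar only.
- First-order temporal accuracy (the stored-cycle quantities are dominated
  by spatial error at the default time step).
- The Quemada γ_c is calibrated to the published idealized baseline because
  the source parameterization is unpublished; with the literature γ_c the
  qualitative conclusions are unchanged but the non-Newtonian shift is
  ~50% larger.
- The outlet resistance affects only the reported pressure level in these
  single-outlet domains.
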