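# Methods

## Scope and modelling stance

`atriumflow` is a desk-scale re-implementation of a right-atrial
catheter-haemodynamics analysis.  The published full-resolution studies
of this problem run multi-million-element 3-D meshes for tens of hours on
HPC clusters; their absolute haemodynamic values are not reproducible on
a workstation and are not this package's target.  Instead the package
preserves every modelled *mechanism* — pulsatile caval inflow, a
generalized-Newtonian fluid, jet/chamber interaction of a catheter's
return flow, tracking of the filtered-blood phase, and the complete set
of derived statistics — at a scale where each operator is verified
against analytic solutions.  The metric formulas themselves (vorticity,
strain/stress, recirculation fraction, tip statistics, convergence
errors, correlations) are scale-independent and are certified exactly.

## Fluid model

Blood is incompressible with density ρ = 1060 kg/m³ and a Bird–Carreau
shear-thinning viscosity

μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)²]^((n−1)/2)

with defaults λ = 3.313 s, n = 0.3568, μ0 = 0.056 Pa·s,
μ∞ = 0.00345 Pa·s.  γ̇ = 0 is a valid input (the law is finite there); no
regularisation is applied.  The shear rate entering the law is identified
with the strain-rate magnitude |ε| = √(2 ε_ij ε_ij) — the standard
generalized-Newtonian convention — both in the solver and in the stress
metric τ = μ(|ε|)|ε|.  A Newtonian comparator (μ = 0.004 Pa·s) shares the
same interface; setting μ0 = μ∞ reduces the Carreau law to it exactly,
which the tests exploit as an equivalence oracle.

## Chamber geometry

The chamber is a 2-D rectangle (default 6 cm × 6 cm, 48×48 cells) with a
uniform out-of-plane depth (default 3 cm).  Openings are boundary slots:
the two caval inlets on one wall (slot areas matching the circular areas
of the 17.06 mm and 16.89 mm vessels), the tricuspid outlet opposite
(9.95 cm²), and catheter lumen slots on the top wall.  Using a single
depth for all patches makes the in-plane mass balance and the physical
flow-rate balance identical, so rigid-wall continuity
(Q_in(t) = Q_out(t)) holds to machine precision at every step.

The catheter solid is not resolved.  Each lumen is a source/sink patch:
the venous slot injects the operating flow (400 ml/min) carrying phase
value 1; the arterial slot withdraws the design's achieved flow
(350–380 ml/min).  Design A splits a configurable fraction (default 50%)
of the venous flow over side-hole sub-slots.  Slot velocities are
*flow-rate preserving* — the quantity the mass-based recirculation
fraction depends on — while the true lumen jet speed Q/A_lumen
(≈ 0.855 m/s for design D) is computed and exposed separately; a 2-D
grid-width slot cannot honour both at once, and flow-rate fidelity was
chosen because R_f is a mass-weighted statistic.  Published tip
coordinates are not available, so tip positions are encoded by their
described relations: position 1 mid-chamber, position 2 translated
toward the wall, position 3 (asymmetric tips only) mirroring the lumen
order, the planar analogue of rotating the tip about its axis.  The
per-design venous–arterial separations (10/10/15/20 mm for A/B/C/D)
encode only the qualitative separation ordering of the tip morphologies.
Reverse mode swaps the venous and arterial patch roles.

Only the 2-D chamber solver is implemented; the metric operators
(vorticity, helicity, strain/stress, tip statistics) are fully 3-D
capable and are tested on 3-D analytic fields.  A coarse 3-D box solver
would add numerical surface without adding a verifiable mechanism.

## Boundary conditions

A periodic two-peaked venous pressure waveform (dominant a-wave in late
diastole, secondary v-wave in systole) is generated parametrically: mean
gauge pressure (default 3 mmHg, the normal volume-averaged right-atrial
value), pulse amplitude (default 2 mmHg), and peak-timing fractions; its
trapezoidal time-average equals the requested mean by construction, and
users may instead load a sampled waveform from CSV.  The waveform is
applied identically and spatially uniformly at both caval inlets.
Because pure pressure boundary conditions are under-determined without
the full 3-D geometry, inlets are velocity-driven by default: the
waveform maps to inflow speed through a linear admittance
(default 5×10⁻⁴ (m/s)/Pa, placing the mean caval velocity near the
clinically reported 0.17 m/s).  The tricuspid outflow is balanced each
step from global continuity.  All pressures are gauge, referenced to the
outlet at 0 Pa.

## Numerics

Staggered (MAC) grid; fractional-step projection:

1. **Momentum** — explicit first-order upwind advection; first-order
   implicit (backward-Euler) diffusion with cell-wise apparent viscosity,
   solved directly per component (sparse LU).  The viscous term uses the
   simplified form ∇·(ν∇u), identical to the full stress divergence for
   constant viscosity (all analytic oracles) and a standard approximation
   otherwise.  No-slip walls use a quadratic ghost extrapolation through
   the wall value, making the wall flux exact for quadratic profiles;
   the steady plane-Poiseuille solution is then nodally exact, and the
   one-sided second-order wall-shear formula recovers τ_w = 4μU_max/H to
   machine precision.
2. **Projection** — a pressure Poisson solve (Neumann, one cell pinned,
   pre-factorised) enforces the discrete divergence to machine precision;
   the per-step continuity residual is monitored against the 10⁻⁴
   tolerance.
3. **Phase transport** — the two-phase model with identical material
   properties reduces exactly to one advected bounded scalar ∅r.  It is
   advected in conservative flux form: donor-cell upwind (provably a
   convex combination for divergence-free face velocities at CFL ≤ 1),
   or van Leer MUSCL fluxes limited by a Zalesak flux-corrected-transport
   step (default).  Both keep ∅r ∈ [0, 1] in exact arithmetic; the
   solver tolerates only round-off-level excursions (> 10⁻¹² aborts) and
   removes them.  The advective Courant number (|u|+|v|)Δt/h is capped at
   0.9 with automatic sub-stepping (or an abort when adaptivity is off).

Time steps default to 0.005 s (single phase) and 0.001 s (with phase
tracking); runs last 4 cycles by default and the final cycle is the
analysis cycle.  The solver is deterministic: the only randomness is an
optional seeded initial perturbation (amplitude 0 by default), and
identical configurations reproduce bit-identical snapshots.

## Metrics

All discrete derivatives in the metric operators are central differences
(second order in the interior).  Time averages are trapezoidal over
exactly one cycle; volume averages are arithmetic means (uniform cells).
The recirculation fraction follows the mass-weighted definition: facet
time-averages ∅̄_k, facet mass flows ṁ_k = ρ(u_k·A_k) time-averaged,
R_f = Σ ∅̄_k ṁ_k / ṁ_T × 100.  Tip statistics are evaluated on the cells
whose centres fall in the design's rectangular sampling prism
(per-design dimensions; anchored under the venous exit): volume-averaged
τ̄ and the volume percentage with τ ≥ 10 Pa.  The threshold comparison is
inclusive (≥); the printed sources alternate between ≥ and >, a
measure-zero distinction on continuous fields.  Helicity is implemented
as the kinetic helicity density u·ω (identically zero for planar fields),
its role being visual/diagnostic only.

## Synthetic data and what passing tests show

The generators emulate each input class with *planted* ground truth:

- analytic fields (Poiseuille, rigid rotation, Taylor–Green, ABC) carry
  closed-form vorticity/strain/WSS for operator oracles;
- phase patterns plant R_f exactly by constructing facet fractions whose
  mass-weighted mean hits the target, plus zero-trapezoid-mean wiggles;
- pulsatile series plant per-cycle convergence errors exactly (cycle
  boundary samples are chosen so each cycle's trapezoidal mean is exact);
- correlated pairs plant the *sample* Pearson coefficient exactly via
  Gram–Schmidt mixing, so recovery tests are sharp;
- supplementary-schema mocks write these series in the CSV/XLSX layout
  the validation reader consumes, making the writer/reader/statistic
  chain round-trip-testable.  They are synthetic stand-ins, not study
  data.

Passing tests therefore certify the correctness of the formulas,
schemas, and solver mechanics.  They do not certify patient realism: the
synthetic series lack physiological variability, measurement noise and
3-D flow structure, and the 2-D chamber's absolute vorticity/WSS levels
sit below in-vivo bands (the band check reports this rather than hiding
it).

## Problem sizes

Defaults follow the operating tables (48² grid, 4 cycles, Δt per phase
mode).  The test suite and examples choose smaller sizes — 16²–32² grids,
1–2 cycles, channel oracles at 8–16 cells across — selected so the whole
suite completes in well under a minute while every property (2% Poiseuille
accuracy, order-of-accuracy gains, exact boundedness, bit determinism)
is still discriminating.

## Known limitations

- 2-D idealised chamber: no realistic atrial anatomy, no third-dimension
  mixing; absolute haemodynamic levels are not comparable to 3-D values.
- Rigid walls, no tricuspid-valve function, no fluid–structure
  interaction, no catheter tip motion.
- First-order upwind momentum advection is diffusive; it bounds, rather
  than resolves, fine vortical structure at the default grids.
- Variable-viscosity diffusion uses the simplified Laplacian form.
- Pressure-driven inlet mode is represented through the linear admittance
  map rather than an outer fixed-point iteration on inlet pressure.
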