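# Methods

## Governing models

**Pore scale.** The medium (culture-medium defaults µ = 1.0 mPa·s,
ρ = 1000 kg/m³) is Newtonian and incompressible. At perfusion velocities
of order 100 µm/s through pores of order 100 µm the Reynolds number is
0.1–0.3, so the momentum balance is taken in the creeping (Stokes) limit:
∇·v = 0, µ∇²v − ∇p = 0. Dropping inertia buys exact linearity — the
permeability is independent of the driving strength, and velocity/pressure
fields scale exactly with the inlet condition, which the test suite
exploits. Every solve reports Re = ρū·d_pore/µ (d_pore = 4V_fluid/S_wall)
and warns above 1.

**Homogenization.** Each RVE spans the full scaffold height, so the axial
Darcy permeability κ = QµH/(AΔp) with A the *full* cross-section
(solid + fluid) is the only effective property the macro model needs.
Aggregation over RVEs is the arithmetic mean (geometric/harmonic
alternatives would matter only for strongly heterogeneous κ; the macro
model is used solely to produce pressure boundary conditions, for which
the arithmetic mean of near-lognormal samples is adequate and simplest).

**Macro scale.** Instead of coupling a Darcy domain to a Navier–Stokes
domain through explicit interface conditions, the channel is solved as a
single Darcy–Brinkman problem: µ∇²v − (µ/κ_loc)v − ∇p = 0 with
κ_loc = κ̄ in the scaffold region and the drag off in the free fluid. In
the creeping regime this is equivalent to the segregated formulation and
enforces continuity of normal mass flux across the fluid–porous interface
by construction.

**WSS.** On every fluid–solid interface face the tangential viscous
traction is computed from a one-sided difference of the tangential
velocity at the adjacent fluid cell center (no-slip makes the wall value
exactly zero): τ = µ|u_t|/d. WSS is reported in mPa, the unit the
mechanobiology thresholds are quoted in.

## Discretization and solver

Geometry is voxel-native end-to-end: a binary fluid mask on an isotropic
lattice, flow axis z, 6-connectivity for percolation and face-based wall
detection, matching the solver stencil. Fluid not 6-connected to both
z-faces carries no flow, would make the pressure system singular, and is
removed (reported as trapped porosity).

The discretization is a marker-and-cell (MAC) staggered finite-volume
scheme: pressures at fluid cell centers, face-normal velocities on
fluid–fluid faces. No-slip enters through mirror ghosts at half-voxel
distance, so walls are exact by construction. Boundary conditions:
velocity inlet (uniform normal velocity, tangential pinned to zero),
pressure inlet (uniform ghost pressure one cell spacing below the first
cell plane, free tangential slip), outlet reference pressure (same ghost
construction), lateral faces either no-slip or symmetric (zero normal
velocity, zero normal gradient of tangential velocity). The Brinkman drag
adds (µ/κ)h³ to the face diagonal, with the face κ taken as the
arithmetic mean of the adjacent cells.

The symmetric saddle system is equilibrated (velocity rows by
diag(A)^-1/2, pressure rows by the SIMPLE Schur diagonal
diag(Gᵀdiag(A)⁻¹G)^-1/2) and solved by MINRES with an SPD block-diagonal
preconditioner: one smoothed-aggregation multigrid V(1,1) cycle per
velocity component (geometric 2×2×2 aggregation on the face lattice,
damped-Jacobi-smoothed prolongators, Galerkin coarse operators, direct
coarse solve) and identity on the equilibrated pressure block. Systems
below 20k unknowns go through a sparse direct factorization instead,
which makes the tight-tolerance linearity checks exact to rounding.
Convergence is declared when the root-mean-square mass and momentum
residuals, relative to their zero-field initial values, both fall below
`tol` (default 1e-4, the conventional CFD criterion; oracle tests run at
1e-8 to 1e-10). Converged fields are audited for inlet/outlet flux
mismatch against 10·tol.

### Numerical choices worth knowing

- **Permeability Δp sampling.** For pressure-driven solves Δp is the
  prescribed ghost difference acting over (nz+1)·h — an exact end-to-end
  measurement, and what the pipeline's permeability probe uses (a nominal
  0.5 Pa; κ is scale-free by linearity). For velocity-driven solves the
  forced uniform inlet causes a genuine entrance pressure loss, so the
  axial gradient is estimated by least-squares regression over interior
  planes (margin nz//8). On columns only a few pores tall the regression
  weights the interior and can deviate from the end-to-end resistance;
  this is why the pipeline probes with pressure, keeping the
  permeability consistent with the pressure-handoff stage (the
  self-consistency test holds the loop to 10%, and measures ~0.5%).
- **Macro interface pressures.** Plane pressures on the porous faces are
  extrapolated from the two cell layers *inside* the porous region;
  interpolating across the fluid–porous interface would smear the kink in
  the pressure profile and bias Δp low by half a cell.
- **WSS surface model.** The default `smoothed-normal` mode estimates the
  local orientation of the underlying smooth surface from the gradient of
  a Gaussian-blurred (σ = 1.5 voxels) solid indicator and corrects both
  the sampling distance and the element area by the face/surface cosine
  (clamped at 0.25). This removes most of the staircase bias of voxelized
  curved walls: on a 10-voxel-radius tube the literal `staircase` mode
  underestimates the mean WSS by ~20% and overestimates the area by 4/π,
  while the corrected mode is within ~3% of 4µu/R with the true lateral
  area recovered. Plane walls are unaffected (cosine = 1). `staircase`
  remains available for comparison.
- **Degenerate inputs.** Zero inlet forcing returns an identically zero
  field without iterating; blocked (non-percolating) domains and
  non-positive pressure drops raise immediately; empty wall sets produce
  an empty WSS field with a warning.

## Synthetic scaffolds

The generator thresholds a Gaussian random field smoothed to a
correlation length set by the requested mean pore diameter (kernel
σ = d_pore/4 in voxels, fixed once from chord-length measurements at
porosity 0.5), removes non-spanning fluid, and re-adjusts the threshold by
bisection until the percolating fluid fraction matches the target
porosity within ±0.02. This reproduces what matters for the method —
irregular, non-repetitive, interconnected pores with controllable
porosity and pore size — but not everything about real scaffolds: no
anisotropy, no strut-thickness distribution, no surface roughness below
the voxel scale, no closed-cell walls. Passing validation on these
geometries therefore demonstrates the *consistency of the multiscale
chain*, not the accuracy of any particular physical scaffold's WSS.

## Study conditions and problem sizes

The validation analogue runs on 64³ scaffolds (10 µm voxels, 0.64 mm
cube) at porosity 0.8 with 80 µm mean pores, a single central RVE of half
the footprint (0.32 mm), macro channel with one scaffold height of free
fluid at either end and no-slip walls, inlet superficial velocity
500 µm/s, and five subregion annuli of 32 µm tiling the RVE half-width.
The 80 µm pore size preserves the RVE-to-pore ratio (~4) of the physical
studies this emulates — an RVE must cover at least one full pore to be
representative. Ten seeds form the study set; histograms use 5 mPa
area-weighted bins over [0, 100] mPa with an overflow bin (binning is a
reporting choice; weights conserve total wall area under any width).

At these sizes a full 64³ direct solve takes tens of seconds on one CPU
core and the complete ten-seed study under ten minutes; the acceptance
script runs three seeds.

## Known limitations

- The symmetric lateral RVE boundaries forbid inter-RVE flow; the
  resulting error concentrates near the RVE boundary. In the ten-seed
  study the outermost subregion carries the largest percent error in the
  majority of seeds, but in seeds where the two approaches agree within
  ~7–14% everywhere the region ranking is noise-dominated, so the
  "boundary region worst" signature is not universal at this scale.
- Voxel (staircase) geometry: WSS accuracy on curved walls relies on the
  smoothed-normal correction; the refinement study (gap of 10/20/40
  voxels) documents the convergence behavior.
- Scalar axial permeability only; the full tensor would need three
  orthogonal solves and is not consumed by the macro model.
- No inertial (Forchheimer) or slip corrections; no transient perfusion;
  no cell-seeded (partially occluded) geometries.
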