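# Methods

`rhizoflow` computes macroscopic hydraulic properties of variably
saturated soil from three-phase (soil/water/air) voxel images by
homogenization: pore-scale Stokes flow on the water domain of a
representative elementary volume (REV) is upscaled to Darcy's law, and
the resulting conductivity–saturation and retention curves are condensed
into van Genuchten parameters.  This note records the model, its
assumptions, the numerical choices, and what the synthetic test media do
and do not establish.

## Flow model and upscaling

Pore water at typical soil pore sizes is deep in the viscous regime, so
inertia is neglected (Stokes limit).  The air–water interface is held
fixed over a solve, and trapped air is treated as a rigid, stationary
obstacle; both fluids' interfaces with soil and air are no-slip for the
water.  This excludes moving-interface dynamics and air lubrication: a
connected, mobile air phase would increase conductivity beyond what the
model reports.

Homogenization requires a periodic microstructure.  Real samples are not
periodic, so an image-based periodicity is enforced by mirroring the REV
in x, y and z, which makes the 8x-larger reflected cell truly periodic
by construction.  On the reflected cell, three corrector (cell) problems
— one per driving direction k — determine the permeability:

    -∇²ν_k + ∇π_k = ê_k   in Ω_w (water domain)
         ∇·ν_k = 0        in Ω_w
           ν_k = 0         on soil/air interfaces Γ

with periodic outer boundaries, or, equivalently and at half the domain
size per axis, mirror-symmetry conditions on the un-reflected sample: on
the two faces normal to k, π_k = 0, ∂(ê_k·ν_k)/∂x_k = 0 and zero
tangential velocity; on the other faces, zero normal velocity and zero
normal gradient of pressure and in-plane velocity.  The driving force
sign is chosen so corrector velocities are non-negative on average.  The
permeability is the cell average

    K_jk = (dx²/μ) ⟨ê_j · ν_k⟩,

with dx the voxel edge and μ = 10⁻³ kg m⁻¹ s⁻¹; the normalization is
fixed by requiring the plane-Poiseuille limit K = φ a²/(12 μ) (slab of
aperture a occupying volume fraction φ) to hold, which the test suite
verifies against closed-form and series solutions.  Hydraulic
conductivity is K_h = ρ g K_kk (ρ = 10³ kg m⁻³, g = 9.8 m s⁻²),
reported in cm/s.  The same ρ and g convert matric potential to head:
1 kPa = 10.2041 cm of water.

### Off-diagonal permeability

The effective tensor of the *reflected* cell is diagonal: under the
mirror in axis j, the j-component of the k-corrector (j ≠ k) is odd, so
its full-cell average vanishes identically.  Symmetric-mode results are
therefore diagonal by construction (the half-domain averages of the
tangential components are retained on each solution as diagnostics, but
they are not entries of the upscaled tensor — each direction's
symmetric-mode problem has direction-specific boundary conditions, so
those averages obey no reciprocity).  A full tensor with meaningful,
exactly symmetric off-diagonals (b_jᵀu_k = u_jᵀA u_k with one shared
operator A) is available by solving a geometry as its own periodic unit
cell (`mode="periodic"`).

## Discretization and solver

The cell problem is discretized with a staggered (MAC) finite-difference
scheme directly on the voxel grid: pressure corrections at cell centres,
velocity components on cell faces, walls honoured halfway between voxel
centres (an interface face is an exact zero; a tangential wall enters
the stencil through a reflected ghost).  No meshing step is involved;
at matched resolution this is equivalent to meshed finite-volume
treatments of the same geometry.  The symmetric-boundary discretization
is derived by algebraically folding the periodic discretization of the
reflected cell (symmetry-plane through-flow faces carry row weight 1/2),
so the two formulations agree to solver tolerance — the central
correctness oracle of the test suite, which holds at ~10⁻¹² relative in
practice.

The saddle-point system [[A, G], [Gᵀ, 0]] is solved either by sparse LU
(below ~15k unknowns; beyond that fill-in makes it slower than
iteration) or by MINRES with a Jacobi block preconditioner (velocity
diagonal; identity on pressure), relative tolerance 10⁻⁸ by default.
The pressure gauge of any fluid component that does not reach a π = 0
boundary (enclosed pockets; all components in periodic mode) is fixed by
adding a unit diagonal pin to one continuity row per component; the
pinned row is linearly dependent on the others, so the solution is
unchanged and the matrix stays symmetric.  Isolated water retains its
unknowns and self-consistently carries zero net flow.  An all-fluid cell
is rejected: with no no-slip surface the net body force cannot be
balanced and no steady solution exists.

Properties the discretization inherits exactly (and the tests assert):
diagonal K ≥ 0 (energy identity: the weighted force–velocity product
equals the viscous dissipation); domain monotonicity (removing water
voxels can only reduce K — the variational space shrinks and the energy
form grows); plane-Poiseuille mean velocity equal to φ(a²+2)/12 in voxel
units, i.e. second-order convergence to the continuum.

## Synthetic media

No public image data accompany the workflow, so the package generates
three-phase media that emulate the two texture archetypes:

* **sand_like** — random sequential addition of spherical grains with a
  rejection rule on centre separation.  Grains may interpenetrate by at
  most `max_overlap` (default 0.35) of the smaller radius: strict
  non-overlap jams near 38% solids, far looser than a repacked sand, and
  bounded interpenetration is the simplest way to reach realistic
  porosities (default target 0.45) while keeping granular morphology.
  Insertion stops at the porosity target; the worst-case overshoot is
  one grain volume and the generator fails loudly if the target is
  missed by more than 0.03.
* **clay_like** — an aggregated matrix: voxels near the boundary between
  the two nearest aggregate centres (centres evenly spread by a
  minimum-separation rejection rule) form a thin inter-aggregate
  micropore network whose width is bisected to meet the porosity target,
  plus `crack_count` penny-shaped planar macropores in a grid-aligned
  parallel family with rounded rims.  Three geometric choices keep the
  pore-radius distribution honestly bimodal rather than smeared: cracks
  are grid-aligned (a tilted slab's staircase boundary spreads its
  thickness signature), rims are rounded (a sharp edge carries
  arbitrarily small inscribed radii), and a solid collar separates
  cracks from micropores.  Micropore pockets thicker than 2.5 voxels
  (where several boundaries meet) are re-solidified.

The default voxel size is 1 μm.  This is finer than typical soil-core
CT (~10 μm), deliberately: with the 0 to −75 kPa schedule the
Young–Laplace critical radius spans 28.8 → 1.92 μm, so at 1 μm a 64³
grid resolves both macropores that drain early and micropores that stay
water-filled at −75 kPa.  At a CT-like voxel the whole resolvable pore
population drains by −20 kPa and the texture contrast cannot exist at
desk-scale grids.  Grain/aggregate radii default to fractions of the
grid (8–14 voxels for grains at 64³) so the media remain well-resolved
at smaller test sizes; the scaling is morphological, not a granulometric
claim.

### Drainage

Quasi-static drainage follows the capillary-bundle reading of
Young–Laplace with invasion percolation: at potential P (kPa), air
occupies pore voxels whose local pore radius is ≥ r_c = 2σ cosθ_c/|P|
(σ = 0.072 N/m, θ_c = 0 by default) *and* that connect to the invasion
face (top, configurable) through voxels meeting the same criterion or
already-drained air.  Face (6-)connectivity is used for invasion —
edge/corner contact cannot transmit flow — while object counting uses
the permissive 26-connectivity.  Air never reverts to water: only the
drainage branch is modelled (no imbibition, films, gravity within the
sample, or shrinkage).  Local pore radius is the local thickness: the
radius of the largest inscribed sphere covering each pore voxel,
computed from the Euclidean distance transform (surface taken half a
voxel beyond pore-voxel centres) followed by a descending covering
sweep with a one-voxel tolerance that absorbs staircase artefacts.
When r_c falls below one voxel the step degenerates to full drainage of
connected pores, with a warning.

Because air accumulates monotonically, the water domains along a
schedule are nested, and with discretization fixed the solved K_h(h) is
monotone non-increasing exactly — a pipeline-level invariant the
acceptance tests exploit.

## Retention model and fitting

The van Genuchten model with θ_r = 0,

    θ(h) = θ_s [1 + (αh)ⁿ]^(−m),    m = 1 − 1/n,
    k_r(h) = {1 − (αh)^(n−1) [1+(αh)ⁿ]^(−m)}² / [1+(αh)ⁿ]^(m/2),

is fitted to the imaged θ(h) and computed K_h(h) jointly by nonlinear
least squares over (θ_s, log α, log(n−1)): θ residuals normalised by the
saturated water content, conductivity residuals on log₁₀ scale (K spans
decades), each dataset weighted by the inverse square root of its point
count so both contribute equally in aggregate.  K_sat is the computed
conductivity at h = 0, reported alongside but not fitted.  Optimization
is multistart from a 5×5 grid (α ∈ [0.005, 0.5] cm⁻¹ log-spaced,
n ∈ [1.15, 3.5]); the best start wins.  Noiseless round trips recover
generating parameters to 10⁻⁴ relative; at θ-noise σ = 0.01 the median
relative error in n stays below 5% over 100 replicates.  Fewer than four
distinct heads, or flat retention data (e.g. a clay that barely drains
over the schedule), are rejected as degenerate rather than fitted.

## REV convergence

Cubic subsamples are drawn at seeded-random origins (overlap permitted;
origins logged and reused across the potentials of one sample).  Each is
refined into a dyadic series V_j = V_0/2^j, j = 0…8, of concentric
cubes — centred, to avoid boundary bias — with sides rounded to whole
voxels (the achieved side is what enters the K scaling) and truncated
below 4 voxels.  Statistics (mean, SD of K_h per level) quantify
convergence toward the sample-scale conductivity; a level is flagged
converged when its mean moves less than a configurable fraction (default
10%) from the next larger volume.  Negative mean-minus-SD bands at small
REVs reflect scatter, not negative conductivity: per-solve K is
provably non-negative here.

## Segmentation, noise rule and pore metrics

Greyscale volumes are segmented by two reference-calibrated cuts: the
air/water cut halfway between the air grey (defaulting to the
histogram's lowest mode, since only water and soil references are
physically calibrated) and the water reference, and the water/soil cut
halfway between the water and soil references.  Partial-volume voxels
are thus arbitrated by nearest reference — a choice, stated here, not a
claim about any particular scanner.

The noise-exclusion rule removes connected non-soil objects smaller
than two voxels in any bounding-box axis or below a volume cutoff that
defaults to (2·voxel)³ — 8×10⁻⁶ mm³ at a 10.17 μm voxel — with a
per-slice 2D analogue (0.02 mm minimum diameter at that resolution).
Removed specks take the majority phase of their face neighbours, ties
broken toward water so filtering never invents solid.  The filter is
idempotent and conserves total volume.

Pore metrics treat an AFP/WFP as a single 26-connected region of air or
water.  Surface areas come from marching cubes on a lightly
Gaussian-smoothed (σ = 0.7 voxel) phase mask — raw binary marching
cubes inherits voxel staircasing and overestimates smooth-object areas
by several percent (digitized spheres land within 3% of 4πr² with
smoothing; voxel-face counting errs by up to ~50%) — while thin
one-voxel films stay above the iso-level and are not lost, though their
areas are less accurate.  The air–water interface counts toward the
total boundary of both phases; the solid-contact/fluid-contact split of
the water surface is reported separately as a voxel-face count, since a
triangulated surface is not partitioned by contact type.

## Pipeline and reproducibility

The pipeline (generate → drain → filter → metrics → subsample → solve →
fit) is driven by a YAML config with every seed explicit; rerunning an
identical config reproduces byte-identical numeric outputs, and the
generate/drain stage is cached on disk keyed by a config hash.  The
"bulk" vs "rhizosphere" presets differ only in porosity target and
crack count (densification reducing macroporosity); they are parameter
presets for the comparison workflow, not an asserted structural model of
rhizosphere soil.

## Problem sizes

Default study sizes keep a full run on one CPU in minutes: synthetic
media at 64³ (1 μm voxels), REVs of 32³ with dyadic refinement to 4
voxels, reflection checks at 32³-vs-64³, and tensor ensembles at 32³.
All sizes are configuration, not constants, and scale up unchanged.

## Limitations

* Fixed-interface, rigid-air Stokes flow: no moving menisci, film flow,
  or air-phase mobility; conductivities near saturation of a connected
  air phase are underestimates.
* The drainage branch only; hysteresis is represented solely by air
  never re-wetting.
* Synthetic media reproduce pore-scale morphology classes (granular
  interstices vs bimodal aggregate/crack networks), not particle-size
  distributions, mineralogy, shrink–swell, or sub-resolution porosity;
  passing tests demonstrate the pipeline's physics and numerics, not
  agreement with any specific field soil.
* Reflection-based periodicity biases small REVs (error decreasing with
  REV size); the dyadic convergence series is the instrument for judging
  when that bias is immaterial.
* Voxel-native no-slip places walls at half-voxel offsets; narrow
  throats of 1–2 voxels carry O(1) discretization error even though the
  analytic oracles converge at second order.
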