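# Methods

## The score and what it claims

After endovascular coiling, the fluid-facing surface of the coil mass
(the coil plane) is loaded by the parent-artery flow. The
pressure-difference score

    PD = (Pmax − Pave) / (½ ρ Vin²)

measures the pressure elevation at the coil plane relative to the inlet
dynamic pressure: `Pmax` is the highest pressure sampled on the coil
plane, `Pave` the mean pressure and `Vin` the mean through-plane velocity
on an inlet section 1 mm proximal to the aneurysm neck, and ρ the blood
density. The normalization makes PD dimensionless and comparable across
patients when a uniform inflow condition is imposed; high PD on the coil
mass is the proposed mechanism for coil compaction and recanalization.
All quantities are evaluated at peak systole, the instant of maximum
inlet velocity within the analyzed cardiac cycle.

Two model variants of a treated aneurysm are compared. The *virtual*
post-coiling model (VM) removes the dome by a flat planar cut through the
neck — an idealization of complete obliteration constructible from
pre-treatment anatomy. The *real* post-coiling model (RM) has an uneven
coil surface; here it is a surrogate: the flat cut displaced into the
dome by a seeded, spatially correlated elevation field (patient coil
surfaces come from post-treatment imaging, which this package does not
consume).

## Geometry model

Domains are two-dimensional planar channels on a uniform Cartesian grid
(cell-centered, 0-based, meters), masked immersed-boundary style with
labeled patches (`inlet`, `outlet`, `wall`, `coil_plane`, and the
interior measurement plane `inlet_plane`). Dimensionality is the central
scale reduction: a 2-D section preserves the impinging-vs-parallel jet
mechanics that drive PD while keeping transient Navier–Stokes solves in
the seconds-to-minutes range. Consequences: absolute PD magnitudes are
smaller than in 3-D patient vessels (a plane jet spreads differently
from a round jet, and secondary/swirling flow is absent), so PD values
from the solver are compared *between* configurations, never to patient
values.

Parameters (defaults in parentheses):

* `parent_radius` (2 mm) — channel half-width, ICA-like.
* `parent_length` (16 mm) — mother-vessel segment containing the neck.
* `dome_radius` (3 mm), `neck_width` (3 mm) — circular dome and the
  opening connecting it to the vessel; `neck_width ≤ 2·dome_radius`;
  `dome_radius = 0` degenerates to a straight tube.
* `dome_offset_angle` — 0 places the dome on the side wall of a straight
  vessel (post-coiling flow parallel to the coil plane); values in
  [π/4, π/2] bend the parent artery by that angle at the neck and place
  the dome in line with the upstream axis (terminal type; the jet
  impinges on the coil plane). Intermediate dome tilts without a bend
  are not modeled.
* `branch` — optional PcomA-like straight branch (radius < parent
  radius) leaving the junction; it adds a second outlet, and the coiling
  cut never removes branch cells, so the ostium stays patent.
* `inlet_extension` (75 mm) — proximal passage before the neck. Because
  the inflow profile is prescribed fully developed (parabolic), the
  extension's physical purpose is already met at much shorter lengths;
  tests and examples use 4–10 mm and state so. The measurement plane
  sits 1 mm proximal to the neck's proximal edge regardless.

The VM cut plane passes through the neck parallel to the local
parent-vessel axis: the wall-tangent line for the side-wall case, the
plane parallel to the downstream-leg axis (facing the jet) for the bent
case. The RM elevation field is white noise on a half-cell lattice along
the cut, smoothed with a Gaussian kernel of the configured correlation
length (default 1 mm), then rescaled to [0, amplitude·neck_width]
(default amplitude 0.15 of the neck width). The one-sided field bulges
into the dome — a residual pocket above the coil mass, the geometry
recanalization starts from — and makes amplitude → 0 reproduce the VM
cut exactly while keeping the |displacement| bound tight. A signed field
would in any case be clamped at the vessel wall. Roughness pockets
disconnected from the lumen by voxelization are re-labeled as coil mass.
All stochastic geometry is a pure function of (spec, coil spec, seed).

## Flow solver

Incompressible Newtonian flow (ρ = 1100 kg/m³, μ = 0.0036 Pa·s) with a
fractional-step (projection) scheme on a staggered MAC grid: explicit
first-order upwind advection, second-order central diffusion with
mirror-ghost no-slip at walls, and an exact discrete projection — the
pressure Poisson system is factorized once per geometry (sparse LU) and
solved to machine precision each substep, so the discrete divergence
after projection is at rounding level (the `div_tol` of 1e-8 on
h·|div u|∞/U is enforced with orders of magnitude to spare) and global
mass balance holds identically. Outlets carry a zero-gauge pressure
Dirichlet condition with zero-gradient velocity; the inlet is a
parabolic profile (discretely normalized to unit mean) scaled by the
waveform.

Upwind advection is diffusive at the cell Reynolds numbers reached here;
it buys unconditional robustness and does not affect the verification
suite's accuracy anchor (plane Poiseuille has no advective term), but it
smooths the jet, which is one reason solver PD magnitudes undershoot
patient values. Diffusion and wall treatment are second order: the
Poiseuille centerline error is 0.66 % at the default 0.25 mm spacing and
the observed convergence order under refinement is ≈ 2.

The transient protocol follows the simulation conditions the score was
defined under: reporting interval 0.005 s, cardiac period 0.9 s (the
stated 1.8-s run with two cycles fixes T = 0.9 s), two cycles simulated,
the second analyzed. The waveform is a truncated Fourier series
U(t) = mean·(1 + Σ aₖcos(kωt − φₖ)) with default harmonics
(0.33, 1.0), (0.13, 2.5), (0.05, 4.0): systolic peak ≈ 1.45× mean,
diastolic minimum ≈ 0.6× mean, an ICA-like shape; its cycle average is
exactly the configured mean (0.65 m/s by default, matching the printed
inlet-velocity scale). The published waveform samples are not printed,
so the shape is parameterized and exposed. The solver substeps
internally to satisfy an advective CFL of 0.5 and an explicit diffusion
limit of 0.2 h²/ν while reporting on the 0.005-s grid. Instability
(non-finite or > 50× inflow velocity) raises an error naming the failing
step; the steady driver declares convergence when the per-step velocity
change falls below 1e-6 of the inflow.

## Metric conventions

Decisions the score's verbal definition leaves open, fixed here:

* `Vin` is the area-weighted mean of the inlet-*normal* velocity
  component (flux / area), not the speed — conservation-linked and
  well-defined on a plane.
* `Pave` is area-weighted over faces; each face samples the pressure of
  the fluid cell that owns it (first-order, no interpolation), and the
  staggered layout puts face-normal velocities exactly on faces.
* Peak systole is located from the inlet velocity trace (not pressure);
  ties take the earliest snapshot.
* PD is gauge-invariant (adding a constant to the pressure cancels in
  Pmax − Pave) and invariant under dynamic similarity (u → k·u,
  p → k²·p); both are asserted to near machine precision in tests.

## Synthetic cohort

The generator emulates the published 50-aneurysm cohort: group sizes
7 recanalized / 43 stable, PD in RM 3.40 ± 0.24 vs 1.99 ± 0.75, PD in VM
3.60 ± 0.78 vs 2.15 ± 0.64, maximum size 11.5 ± 2.6 vs 8.3 ± 2.5 mm, VER
22.5 ± 3.5 vs 24.8 ± 4.5 %, PcomA location 7/7 vs 25/43, rupture 5/7 vs
10/43. Marginals: PD and the scalar covariates are normals truncated at
0 (VER also at 100) — at the printed parameters the truncation bias on
the stable-group PD mean is < 0.01; Pave and Vin use moment-matched
lognormals because their printed SDs approach or exceed their means and
a 0-truncated normal would shift the mean far above the printed value.
VM–RM pairs of each parameter are coupled by a Gaussian copula at the
published Spearman coefficients (PD 0.70, Pave 0.561, Vin 0.537;
Spearman ρ_s maps to the copula's Pearson ρ via ρ = 2 sin(πρ_s/6)).
Pmax is not drawn: it is derived from the PD identity
Pmax = Pave + PD·½ρVin², so every record satisfies the score's
definition exactly and the induced Pmax means land within a few percent
of the printed ones. VER is treated as an opaque percentage covariate.

What the generator does *not* emulate: within-patient correlation
between PD and morphology, measurement error structure of the two
imaging modalities, and any physics — passing cohort-level tests shows
the statistical machinery reproduces published discrimination behaviour
under the printed distributions, not that the flow solver would produce
those distributions.

## Statistics conventions

Two-sided p-values throughout; α = 0.05. Mann-Whitney uses exact
enumeration when both n ≤ 8 and the pooled sample is tie-free, otherwise
the tie-corrected normal approximation; U at the null center reports
p = 1 exactly. Fisher's test sums hypergeometric probabilities ≤ the
observed one; a zero margin returns p = 1 with a logged note. ROC
thresholds sit at midpoints between sorted unique scores plus ±∞;
"predicted positive" means score > cutoff (strictly) everywhere — the
convention consistent with 100 % sensitivity at a cutoff below the
smallest recanalized score; AUC is the trapezoid along the threshold
path (equal to U/(n₁n₂) with ties counted ½); the Youden cutoff is the
smallest threshold maximizing sensitivity + specificity − 1. Logistic
regression is IRLS maximum likelihood with Wald intervals on internally
standardized covariates; quasi-separation (non-convergence or a
standardized slope beyond ±15) triggers a refit with a small ridge
penalty (0.1 on standardized slopes, intercept unpenalized) and a logged
warning — near-separation is expected in cohorts of this shape, where
one covariate almost splits the outcome. The multivariate model admits
covariates with univariate p < 0.05 and drops PD-in-VM whenever
PD-in-RM is admitted, mirroring the published selection rule.

## Problem sizes and reproducibility

Test and example solves use 0.25–0.5 mm grids (8–16 cells across the
vessel diameter, the package's chosen desk scale) and 4–10 mm inlet
extensions; a full two-cycle transient on such grids takes seconds. The
acceptance script exercises only the statistics layer (ROC worked
examples and generator calibration at n = 10,000 per group) and runs in
seconds. All randomness flows from a single root seed (the coil-surface
seed is derived from it), every output records the seed and a hash of
the scientific config, and identical (config, seed) pairs yield
byte-identical output files.

## Known limitations

2-D idealized geometry (no patient anatomy, no tetrahedral meshing);
first-order advection; rigid walls; Newtonian rheology; no thrombosis or
coil micro-structure; the RM surface is a statistical surrogate, not an
imaged coil mass; solver PD magnitudes are configuration-comparative
only; the synthetic cohort reproduces printed marginals and pairwise
couplings, not the joint distribution of real patients.
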