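# Methods

`aortastress` re-implements, on synthetic cohorts, a workflow for relating
structural wall stress to aortic growth in acute uncomplicated type B aortic
dissection (TBAD): forward-penalty finite-element wall stress under
reduced-order hemodynamic loading, circumferential growth-rate heatmaps from
longitudinal surface pairs, and a linear mixed-effects test of the spatial
stress–growth association. Units throughout: mm, kPa (stress/pressure), Pa
(wall shear stress), years, %/year.

## Synthetic anatomy

No patient imaging is publicly deposited for this problem, so the package
generates idealized dissected aortas with the geometric structure the
downstream stages require. The outer wall is a structured cylinder-topology
surface (default 50 circumferential nodes x 200 axial layers): a vertical
ascending limb, a semicircular arch in the x–z plane, and a straight
descending limb, with both end rings horizontal so that the axial direction on
the ends is the global z axis. The outer radius follows a PCHIP profile
through a handful of control points: ~16 mm ascending, a dilated dissected
descending segment peaking at 18 mm (36 mm outer diameter, typical of acute
TBAD), tapering to 9 mm at the aorto-iliac bifurcation. The left-subclavian
landmark is pinned to the arch–descending junction (layer 49 by default), the
bifurcation to the last layer, so the descending aorta spans layers 49–200 —
exactly 38 four-layer regions.

The intimal flap is a chord strip across each dissected cross-section, bowed
toward the true lumen (TL) by a configurable sagitta, attached to the luminal
wall surface along two longitudinal lines; the false lumen (FL) is the sector
between the attachments (default 40 % of the circumference, centred on the
outer curvature). The flap carries at least one fenestration — a rectangular
patch of removed quads near its proximal end, standing in for the primary
intimal tear. An optional mural thrombus lines the FL wall over a configurable
axial span (default layers 150–180, 3 mm thick). Wall thickness follows the
double-offset convention: 2 mm TL wall, 1 mm FL wall and flap, so flap + FL
wall reproduce the intact wall thickness.

Patient metadata defaults are population-scale anchors: systolic blood
pressure 18.36 kPa, inlet flow 25 L/min, follow-up interval median 3.18 years
(lognormal), thrombus present in about two thirds of patients. The cohort
generator varies anatomy (radius scale sd 6 %, flap extent sd 0.04), BP
(sd 1.2 kPa) and follow-up interval across patients; every source of
variability is scaled by a single `inter_patient_variation` knob (0 gives
identical patients).

### Ground-truth growth

Each patient's prescribed growth-rate field follows a known linear link to a
closed-form wall-tension pattern (Laplace law p·r/t per node, with thrombus
counted into the load-bearing thickness):

    rate = β0 + b0m + (s* + b1m) · tension + smooth spatial noise

with defaults β0 = −10 %/yr, s* = 0.06 %/(yr·kPa), sd(b0m) = 2 %/yr,
sd(b1m) = 0.02 %/(yr·kPa), spatial noise sd 1 %/yr (correlation length 8 grid
units). These defaults put the cohort in the clinically reported regime:
thin-walled FL segments grow ~5–10 %/yr, thrombosed segments shrink
(negative rates), and the spatially averaged diameter growth lands in the
low mm/year range. The mixed-effects stage therefore has a recoverable ground
truth whose slope units match the reported scale of the association.

The follow-up surface applies the prescribed field by scaling each node about
its ring centroid; because nodewise radial scaling realizes a spatially
varying circumferential strain only to first order, a fixed-point correction
iterates the scale factors until the local circumferential log strain matches
the prescription to 1e-9, making noiseless recovery exact by construction. An
optional rigid transform and Gaussian node jitter emulate scanner pose and
segmentation noise.

## Reduced-order loading

The full CFD stage of the original workflow is replaced by a reduced-order
pressure model — pressure is the quantity that transfers into the structural
solve, and CFD-derived pressure fields are known to change little under full
fluid–structure coupling. Outlet flows follow Murray's law (flow ∝ diameter³,
exact conservation), and resistance-only Windkessel outlets are calibrated as
R_i = (BP − P_distal)/Q_i so the network reproduces the measured systolic
pressure exactly (distal reference pressure defaults to 0; the resistances
absorb the full drop — a modelling convention, as compliance elements are not
needed for a steady systolic load). The TL pressure declines along the axial
coordinate (default 5 % of systolic, linear; exponent configurable); the FL
pressure is uniform at a configurable offset from the TL mean (default
−0.76 kPa, the scale of reported TL–FL mean gaps; sign and magnitude are
per-patient configurable since such gaps are highly patient-specific). Both
flap faces receive their adjacent lumen's pressure; thrombosed luminal faces
are flagged so the solver loads the thrombus lining instead of the wall.

Wall shear stress is a comparator predictor only: a seeded, smooth correlated
random field min–max scaled into the physiological 1–10 Pa band, elevated
near fenestrations. It deliberately carries no flow physics — any smooth
in-band field exercises the statistical machinery identically.

Surface-to-mesh transfer uses inverse-distance-weighted interpolation from
the k = 4 nearest source nodes (power 2), exact at coincident nodes and
constant-preserving; targets farther than 2 mm (the nominal element size)
from any source are counted and surfaced as a warning.

## Forward penalty stress

The solid domain extrudes the outer wall inward along nodal normals into 4
layers of trilinear hexahedra (TL wall 0.5 mm/layer, FL wall and flap
0.25 mm/layer). The thrombus lining is extruded conformingly (shared nodes)
from the FL luminal surface in 2 layers. The flap strip is extruded
symmetrically about its mid-surface; its edge node columns are tied to the
wall luminal nodes at the attachment lines with stiff penalty springs
(node-to-node tie, stiffness 10·E·h) — collapsing the 4-layer flap edge onto
the wall node columns would create degenerate zero-Jacobian hexahedra. All
element corner Jacobians are verified positive.

Material: linear elasticity with the artificially stiff penalty modulus
E = 5·10⁵ kPa (thrombus ratio-locked at E/20 = 2.5·10⁴ kPa), ν = 0.49 with
mean-dilatation B-bar (selective reduced integration) against volumetric
locking. The transmural mean hoop stress of a pressurized tube is
ν-insensitive (<2 % between ν = 0.3 and 0.49 in the suite), so the element
technology choice cannot affect the reported stress. Pressure is a dead
(non-follower) load — displacements are O(10⁻³ mm) at the penalty modulus, so
follower corrections are negligible. Loads are consistent single-point face
tractions (p·A/4 per node along the inward face normal).

Boundary conditions (not specified by the clinical workflow; chosen and
verified here): both end rings are constrained axially, two in-plane point
constraints remove the remaining rigid-body modes, and — default mode
`tethered` — a stiff penalty on each ring's in-plane centroid displacement
emulates perivascular/branch-vessel tethering. Without it the pressurized
arch acts as a pipe elbow and bends the long branch-free descending limb as a
beam (mm-scale displacement at any modulus); patient-specific models avoid
this implicitly by clamping their meshed branch outlets. The tether leaves
radial expansion (zero centroid motion) untouched, verified by the Laplace
oracle. Modes `ends-only` and `clamped` (full end-ring fixation) are
available; the penalty stiffness scales with E so the static-determinacy
factor sweep stays an exact rescaling.

Stress recovery: element-centroid Cauchy stress with the B-bar volumetric
strain, maximum principal value per element, arithmetically averaged through
the 4 layers per surface quad ("transmural average"), then onto grid nodes.
The flap and thrombus are excluded from the transmural wall average.

The direct sparse factorization (SuperLU) makes the solve deterministic at
desk scale. At the default modulus the load-bearing wall displaces < 0.01 mm
on the default dissected case; the 1 mm flap, floating nearly load-free
between near-equal pressures, bends ~0.03 mm and the compliant thrombus
lining ~0.01 mm — displacement bounds for the static-determinacy argument are
therefore reported for the wall node set, with the full-field maximum
alongside.

## Coupled compliant-wall reference

The equivalence check re-solves at physiological stiffness with geometry
updates: solve the linear problem on the current configuration, move the mesh
to (baseline + displacement), re-apply the pressure on the deformed luminal
faces, and repeat until the configuration increment falls below 10⁻³ mm
(max 20 iterations, Aitken Δ² relaxation). Two stabilizations supply the
physics a bare linear re-solve lacks: (i) lagged stress stiffening — the
previous iterate's Cauchy stress enters an initial-stress geometric stiffness
matrix, which is what keeps thin pressurized walls from the end-flare/bulge
feedback that otherwise diverges; (ii) `clamped` end rings for both solves of
the comparison (end effects decay within ~√(rt) of the rings). The compliant
wall modulus defaults to 5·10³ kPa — the incremental circumferential modulus
of older, hypertensive dissected thoracic aortas is a few MPa in the tissue
literature — with the thrombus ratio-locked at E/20. The flap alone keeps its
stiff modulus: at compliant stiffness its net-pressure bending is
geometrically nonlinear (deflection ≫ thickness) and outside what the
iteration can stabilize; it is excluded from the comparison domain anyway.

MAPE between the penalty and coupled fields is the mean over wall surface
quads of |a − b|/|b| (b = coupled reference), flap excluded, quads with
|b| < 1 kPa excluded and counted. On the default dissected case at 25 x 50
resolution this gives ~3.7 %, within the few-percent equivalence reported for
this class of method; `scripts/acceptance.py` recomputes it at 28 x 80
(~12k elements).

## Growth quantification

Baseline/follow-up pairs are pre-aligned with point-to-point ICP (orthogonal
Procrustes per iteration, centroid pre-alignment to avoid the lattice-locked
axial-slide minimum of near-cylindrical surfaces, relative RMS tolerance
10⁻⁸). Correspondence is exact structured-index mapping for synthetic pairs;
a closest-point projection with grid-Laplacian smoothing is the documented
approximate fallback — nonrigid diffeomorphic registration is deliberately
out of scope, and the downstream statistics are agnostic to how
correspondence was obtained.

Circumferential logarithmic strain at each node is ln(ℓ′/ℓ) over the two
incident circumferential segments (wrap-around at the seam); growth rate is
100·ε/Δt in %/year. Optional smoothing for jittered data combines a periodic
circumferential Gaussian with an axial quadratic Savitzky–Golay filter whose
`interp` boundary handling preserves axial trends at the end rings; the
one-sided polynomial windows still inflate noise variance ~3x on the two to
three outermost rings, so jitter-robustness statements exclude a 10-layer
band at each axial end. Per-ring effective diameter is perimeter/π (dissected
sections are not circular), and the per-patient summary is the mean
descending-span diameter change rate in mm/year.

## Regional statistics

The structured grid partitions into 50 axial regions of 4 layers; regions
lying fully between the landmarks are descending (38 with defaults). Region
means pool into the cohort table (9 x 38 = 342 rows), and growth rate is
regressed on stress (and on WSS and pressure as comparators) with a
random-intercept-and-slope mixed model per patient, fitted by REML
(statsmodels MixedLM, unstructured 2x2 random-effects covariance; the
predictor is standardized internally for conditioning and exact
scale-equivariance, and all reported quantities are back-transformed). The
fixed slope is tested with a Wald-type F statistic using between–within
denominator degrees of freedom (ddf = m − 1, because the slope carries a
patient-level random effect; the exact F-test construction of the original
analysis is not stated, so the method tag records this choice). CIs for the
random-slope SD come from a delta-method transform of the REML covariance
parameters. Per-patient Pearson correlations with two-sided p-values complete
the analysis. Monte-Carlo checks at the stated truth (s* = 0.06, sd(b1m) =
0.02, σ_e = 1, 9 patients x 38 regions): slope bias ~1–2 % of s*, 95 % CI
coverage ~95 %.

## Pipeline scale choices

The cohort pipeline quantifies growth on the full 50 x 200 grid, but runs the
FEM on a regenerated coarser copy of the same parametric anatomy (default
25 x 50) and registers the transmural stress back to the full grid by
ICP + nearest-neighbour sampling — mirroring the resampling step of the
original workflow, and keeping a 9-patient run in the minutes range on one
CPU. Region statistics are insensitive to this because they average 4 x 50
nodes per region. The acceptance script's equivalence check uses 28 x 80
(~12k elements) as its single-geometry, higher-resolution setting.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline's arithmetic, mechanics and
statistics are implemented correctly: flow splits conserve, calibration
round-trips, the FEM reproduces closed-form tube solutions and is
material-invariant, prescribed growth is recovered, and the mixed model
recovers known generative parameters with honest coverage. They do not show
that real dissected aortas obey the generative link: the synthetic anatomy is
idealized (no branch ostia meshed, circular outer sections, parametric flap),
the pressure model carries no flow physics, WSS is a statistical stand-in,
and the growth link is linear by construction. Patient-cohort numbers from
imaging studies (specific slopes, p-values, median growth) are emulation
anchors for the defaults, not reproduction targets.

## Known limitations

- Linear elasticity only: no hyperelasticity, prestress, residual stress,
  growth-and-remodeling or failure modelling.
- The coupled reference is a stabilized fixed-point scheme, not a full
  nonlinear FSI solve; the flap is excluded from its compliant domain.
- Point-to-point ICP assumes largely overlapping shapes; closest-point
  correspondence degrades for large non-rigid motion.
- The per-ring centroid tether is a modelling surrogate for perivascular
  support; absolute bending stresses near the arch depend on it.
- Savitzky–Golay end-ring variance inflation limits jitter robustness claims
  to the axial interior.
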