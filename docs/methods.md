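# Methods

## Scope and conventions

All geometry lives in RAS+ world millimetres (x right, y anterior,
z superior); "medial" means toward the mid-sagittal plane `x = 0`.  A voxel
is represented by its centre and NIfTI affines are honoured on load, so the
same code runs on any invertible grid.  Operations that walk coronal slices
(the residual-depth metric) additionally require an axis-aligned affine and
say so.

The package consumes a *parcellated label volume*: parcellation itself
(e.g. by a whole-brain segmentation tool) is out of scope, as are pseudo-CT
synthesis, vascular segmentation, MR thermography and any thermal (bioheat)
simulation.  Sulci serve as critical-structure proxies for vasculature,
reflecting planning practice when no dedicated vascular imaging exists.

## Safety metrics

**Skull surfaces.**  The inner and outer skull surfaces are represented as
signed distance functions.  Two backends exist: a voxel backend (signed
Euclidean distance transforms of the filled intracranial and head solids,
sampled trilinearly) and an analytic sphere.  The synthetic phantom's skull
is an exact sphere, so phantom pipelines use the analytic backend; this is
a deliberate design split — surface positions recovered from a 1 mm
voxelized mask are only accurate to roughly half a voxel, while the
bisection used for surface crossings (0.01 mm tolerance) is much finer.
Closed-form agreement of intracerebral length and drilling angle (line vs
sphere) is therefore checked on the analytic backend, and the voxel backend
is held to voxel-scale tolerances.

**Intracerebral length** is the distance from the first crossing of the
inner surface (bisection along the ray, marching from a point backed off
behind the entry so the start is strictly outside) to the target.
**Drilling angle** is the angle in [0°, 90°] between the trajectory and the
outward outer-surface normal (normalized central-difference gradient of the
signed distance, step 0.5 mm) at the first outer crossing; 0° is orthogonal
drilling.

**Risk.**  Pointwise risk is 1 at or below `d_lo = 3` mm, 0 at or above
`d_hi = 10` mm.  Only the endpoints are prescribed by the planning
protocol; the ramp between them is *linear* as the minimal assumption, and
both endpoints are configurable (`RiskParams`).  Overall risk is the
midpoint-rule path integral of pointwise risk along the intracerebral
segment (default step 1 mm) divided by `norm_length = 10` mm.  A pure mean
over the trajectory cannot reproduce cumulative risks above 1, so the
normalization is an explicit scale constant; any positive scale preserves
the candidate ranking, which is the quantity that matters to the planner.
Halving the sample step changes the integral by well under 2% on phantom
trajectories (tested).

**Minimum distances** (critical structures, brainstem) are minima of the
trilinearly interpolated distance field over the sampled segment, refined
by a bounded 1-D search (0.01 mm tolerance) around the minimal sample.  The
brainstem metric defaults to the minimum over the segment; a
`mode="midpoint"` variant (field value at the segment centre) is provided
because "distance of the centre of the trajectory" is an equally defensible
reading.

**AHC contact.**  The "centre" of the amygdalohippocampal complex is
operationalized as the voxels at least `core_margin = 1.5` mm from the
structure boundary (inside-distance erosion).  The reported proportion is
the trajectory arc length inside that core divided by the AHC extent along
its first principal axis (eigenvector of the voxel-centre covariance),
clipped to [0, 1].  Both the margin and the denominator are documented
choices: no printed formula exists for this quantity, and the erosion
margin trades robustness to mask roughness against sensitivity to genuinely
central passage.  An empty core falls back to the full mask with a warning.

## Planner

The target is *fixed* (no target search): amygdala centroid + (3 medial,
3 anterior, 3 inferior) mm, with the medial sign resolved by side.  Entry
candidates are surface voxels of the active entry-gyrus patch (patch voxels
with a face neighbour outside the intracranial mask), ordered
lexicographically by world (z, y, x) and subsampled on a world grid of
pitch `entry_spacing` (2 mm) anchored at the patch minimum — fully
deterministic, so ties reproduce.

Feasibility rejects, in order: ventricular crossing (exclusion zone,
nearest-voxel sampling at 0.25 mm), clearance below the 3 mm planning
safety margin, drilling angle above 45°.  The objective is a weighted sum

```
score = 1.0·risk − 1.0·ahc + 0.25·length/150 mm + 0.25·angle/90°
```

with non-negative configurable weights; the length and angle normalizers
put all four terms on a comparable ~[0, 1] scale.  No published
multi-objective combination exists for this planning problem, so the
contract tested here is *oracle optimality* — the returned trajectory
matches an independent exhaustive search over the identical candidate set —
plus constraint satisfaction, not specific weight values.  Ties break by
lower risk, then shorter length, then enumeration order.  Roles are tried
in the order inferior occipital → middle occipital → posterior middle
temporal; the first role with any feasible candidate wins and later roles
are never evaluated.  Total infeasibility is returned as a result carrying
the per-reason rejection tally.

## Ablation model

The expected cavity is a flat-capped cylinder of default diameter 15 mm
(valid 5–20 mm, the device's ablation range): distal cap at the target,
proximal cap where the trajectory crosses the coronal tectal plane, since
only hippocampus anterior to the tectal plate is considered for ablation
and volumetrics.  Where the trajectory does not cross that plane a
fixed-length extent is available.  Voxelization uses the voxel-centre
membership rule (reproducible; within 2% of `π r² h` at 1 mm spacing, and
a 5³-supersampled oracle is provided for tests).  Heat-sink effects of
ventricles and cisterns are deliberately **not** modelled — the uniform
cylinder is the model whose estimation error the comparison statistics
quantify.

**Residual mesial-hippocampal-head depth.**  The head region is defined as
hippocampus voxels anterior to the coronal plane through the posterior
border of the amygdala (the structure has no standard quantitative
boundary; this plane is stable and testable).  For every coronal slice
intersecting the head, walk from the medial-most head voxel laterally along
x to the first ablated head voxel; the slice residual is the walked
distance (0 if the medial-most voxel is ablated, the full medial–lateral
extent if nothing is ablated), and the reported depth is the maximum over
slices — a conservative reading of "unablated depth".

## Statistics

Arm comparisons use the unpaired two-sided Mann-Whitney U test (the named
test; a paired design is not assumed).  For pooled sizes ≤ 12 the p-value
is exact by full enumeration of group assignments, which remains valid
under ties because the permutation distribution of U is symmetric about
`n_a n_b / 2`; larger samples use the tie-corrected normal approximation
with continuity correction.  Kruskal-Wallis (tie-corrected, chi-square
reference) covers more than two groups, with the all-identical degenerate
case returned as H = 0, p = 1.  Pearson correlations report a Fisher-z 95%
confidence interval and the t-distribution p-value.  No multiple-testing
correction is applied by default (a Holm option exists).  The cylinder
model's estimation error is `100·(expected − achieved)/anatomical` per ROI,
signed so that positive means the cylinder overestimates.

## Synthetic phantom

The phantom replaces patient parcellations with parametric geometry whose
ground truth is analytic: spherical skull (inner 82 mm / outer 88 mm),
ellipsoidal amygdala (default semi-axes 8×7×7 mm ≈ 1642 mm³, matching a
realistic amygdala volume), capsule-chain hippocampus (radius 5 mm, ~48 mm
arc), temporal/occipital ventricular horn (radius 3.5 mm), parahippocampal
tube, ellipsoidal entorhinal cortex, a cylindrical brainstem, two thin
sagittal sheets standing in for the collateral and occipitotemporal sulci
(1 mm, rasterized to at least one voxel), and three disjoint 5° angular
surface patches for the entry gyri.  Defaults: 192³ grid at 1 mm isotropic,
left-sided pathology, tectal plane at y = −26 mm.  Seeded uniform jitter
(`jitter_mm`, default off; 0.5 mm in the multi-subject tests) perturbs the
soft-tissue centrelines to emulate inter-subject variability.

The default layout realizes the posteroinferior corridor: trajectories from
the inferior occipital patch pass between the occipital horn (above) and
the collateral-sulcus sheet (below) with ~5–8 mm sulcal clearance.  Two
variants close this corridor *by construction* (no quantitative variant
anatomy is published, so the parameters are chosen to guarantee blocking,
and tests verify it exhaustively): `deep_collateral_sulcus` raises the
sheet's dorsal edge by 17 mm and extends it 17 mm anteriorly;
`enlarged_occipital_horn` inflates the posterior horn radius by 5.5 mm and
lowers it by 6 mm.  Both leave a feasible middle-occipital corridor, so the
planner demonstrates the documented fallback.  A `severity` factor scales
the deltas; severity 0 reproduces the base phantom voxel-for-voxel.

What the phantom does **not** emulate: cortical folding (entry "gyri" are
surface patches), MRI intensities and segmentation noise, true sulcal
ribbon geometry, ventricle–hippocampus contact, or population anatomy.
Passing tests therefore demonstrate algorithmic correctness (geometry,
optimality, determinism, volumetric bookkeeping) — not clinical
performance on patient imaging.

A second generator, `planar_risk_phantom`, builds a spherical head with a
single mid-sagittal critical sheet on an odd grid whose voxel centres sit
on integer millimetres; distances to the sheet are then exact under
trilinear interpolation, which makes threshold behaviour of the feasibility
filter measurable to 0.1 mm.

## Numerical choices and problem sizes

Distance fields are exact Euclidean distance transforms (anisotropy-aware)
of voxel masks; sampling is trilinear for continuous fields and
nearest-voxel for membership tests.  Surface crossings bisect to 0.01 mm;
1-D minima refine to 0.01 mm; ventricle exclusion re-samples at 0.25 mm.
The test suite exercises ten jittered 192³ subjects for planner optimality
and a 240³ half-spacing grid for voxelization convergence; these sizes keep
the full suite in the low minutes on a single CPU while leaving every
assertion at its stated tolerance.

## Known limitations

* The cumulative-risk scale is normalization-dependent; only orderings and
  the documented `R = ∫r/10 mm` definition are comparable across studies.
* The mask-backed skull surface carries half-voxel positional uncertainty;
  use finer grids (or analytic surfaces where available) when sub-voxel
  length accuracy matters.
* `residual_mhh_depth` assumes axis-aligned affines and walks voxel
  columns; oblique acquisitions should be resampled first.
* The planner searches entry points only; the target is fixed by the
  centroid transform, and curved or multi-segment trajectories are out of
  scope.
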