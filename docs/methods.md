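# Methods

`spacersim` simulates duodenal hydrogel spacer placement for pancreatic
SBRT on synthetic anatomy, quantifies the separation and dosimetric gain
the spacer buys, and trains a Bayesian decision support system (DSS) that
predicts, before any procedure, whether a spacer helps, where to place
it, and how much biologically effective dose (BED) it unlocks.

## Synthetic anatomy

No patient data ship with the package; a procedural phantom generates the
study cohort. The duodenal C-loop is a tube swept along a circular arc
(285-315 degrees) of radius ~27 mm around the head-of-pancreas (HOP)
target, with outer radius 8-9.5 mm and wall thickness drawn from
2.4-2.9 mm (clinically the duodenal wall is 2-3 mm). The loop is divided
into the four anatomical sections by arc length: D1 (proximal 12%,
adjacent to the stomach), D2 (descending), D3 (horizontal) and D4
(ascending). Per-section radial offsets make the loop irregular: D2 sits
at the reference radius (the pancreatic head nestles against the
descending duodenum), D1 is displaced 2-4 mm outward toward the pylorus,
and D3/D4 draw offsets from U(0, 5) mm. The full tube (wall plus lumen,
~40-50 cc) is the contoured organ used for dose-volume metrics, matching
clinical contouring practice; an explicit `duodenum_lumen` mask defines
the wall (tube minus lumen) used for finite-element meshing.

The target chain is GTV -> GTV_multabc (+3 mm Euclidean dilation, the
mock margin from multiple breath-control CTs) -> PTV (+2 mm setup
margin). The controlling anatomical variable is the minimum HOP-duodenum
gap, drawn from U(0, 4) mm; because the PTV extends 3.5 mm beyond the
HOP surface, this range straddles contact between the PTV and the
duodenum — exactly the regime in which the planning constraints bind.
The stomach (~15-20 cc ellipsoid) interpenetrates the tube by 3 mm and
is carved back to contact, mimicking the contiguous pylorus; the bowel
is a broad, flat-topped blob below the target at a vertical gap of
U(1, 10) mm, wide enough to become dose-limiting in part of the cohort
(so the DSS sees both duodenum-only and multi-organ limited cases).
All draws come from one seeded generator; a seed reproduces a case
bit-identically.

What the phantom does **not** emulate: real duodenal wall folds and
peristaltic shape variability, CT intensity texture (geometry only),
inter-fraction motion, and anatomically detailed stomach/bowel shapes.
Passing tests therefore demonstrate the pipeline's correctness and the
geometry-dose logic, not segmentation-level realism.

## Spacer placement and insertion mechanics

A scenario (S1: D1-D2 interface; S2: +D3; S3: +D4, the full loop) places
lens-shaped pockets in the para-duodenal space: candidate voxels on the
target-facing side of the wall are ranked by distance to the duodenum and
accumulated until the requested per-section volume (default 9 ml, always
< 10 ml) is reached. The placed pocket is the tangent initial
configuration; deformation is the solver's job.

The insertion is a quasi-static, small-strain, isotropic linear-elastic
solve with exact constant-strain 4-node tetrahedra. Surfaces come from
marching cubes (level 0.5 of the Gaussian-smoothed binary field,
sigma 1 voxel, coarsened by step 2 for desk-scale models), smoothed by
volume-preserving Taubin filtering (residual volume change < 1%). The
duodenum is meshed as a conforming wall + lumen-filler model
(`nested_tetrahedralize`): one Delaunay triangulation over both surfaces
and interior lattices, with tets tagged wall or lumen content by
centroid. The filler (E = 1 kPa, nu = 0.49) stands in for luminal
contents; without it the empty cross-section collapses under the push,
which is unphysical and destroys wall-volume bookkeeping. A wall-only
hollow mesh (`hollow_tetrahedralize`) is also provided and tested.
Default materials (duodenal wall E = 5 kPa, HOP E = 10 kPa, nu = 0.45)
are configurable placeholders in the soft-tissue range, not literature
claims; Dirichlet-driven solves make the results insensitive to the
absolute modulus scale.

Anatomical boundary conditions follow the observed behaviour of the
interface: the inferior outer wall of D3 (selected by z below the
section's mean height and an inferiorly pointing lumen-distance gradient)
and duodenal nodes within 2 mm of the stomach are fixed; the HOP mesh is
held at its superior and inferior margins, allowing only local interface
deformation. The 2 mm stomach rule is evaluated against the stomach
surface (voxel-centre distance minus half a voxel).

Contact is projection-based: each pocket is split into <= 40-degree
angular sectors about the loop axis (a single rigid translation cannot
push a long arc outward), each sector advances `push_mm` radially outward
in `n_steps` increments (defaults 8 mm, 6 steps; cohorts draw push from
U(4, 10) mm per case to emulate variable injected volume), and organ
nodes found inside the advancing surface are projected back onto it as
Dirichlet constraints. The contact surface is the pocket dilated by one
voxel (the gel front engages the wall it presses on even where the
discretized pocket thins); when overlapping sectors claim one node the
most advanced front wins. Contact applies to the duodenum model only:
the target is held by its margins and the gel dissects along its
surface. Per-increment strain energies are monotone non-decreasing, a
property the tests assert.

## Deformation field and warping

Node displacements are rasterized to a deformation vector field by exact
barycentric interpolation on the model's own tetrahedra (a Delaunay
interpolator would bridge the lumen with sliver simplices and blend
opposite walls); voxels outside any model take their nearest node's
value, scaled by exp(-(d-h)/10 mm) and tapered to exactly zero at 30 mm.
Voxels inside an organ's mask are always claimed by that organ's model so
one structure's motion cannot bleed into a neighbour across a thin gap.
The field vanishes on the grid border and is capped at 25 mm.

Structures are warped by voxel-wise backward resampling through the
inverted field. Inversion is a damped fixed point (y + u(y) = x,
damping 0.25): expansion zones converge quickly, compression zones
slowly, so after 15 full-grid sweeps iteration continues only on voxels
whose residual exceeds 0.02 voxel. Each organ family is warped with its
own model's field (duodenum family with the wall solution, target chain
with the held target's), which keeps the space vacated in front of the
pushed wall from being back-filled by its unmoved neighbour. Duodenal
sections are re-partitioned from the warped tube by the largest
resampled section weight, so they remain disjoint with union equal to
the tube. The finite-element wall volume is conserved to a few percent;
the voxel-level wall-volume change stays below 10% for pushes up to
10 mm at 2 mm resolution.

## Separation metrics

* **DSC** 2|A∩B|/(|A|+|B|); NaN for two empty masks.
* **OVH**: signed Euclidean distance from every OAR voxel to the target
  surface (negative inside); the overlap curve is sampled at half the
  minimum voxel spacing and L_vcc (v = 1, 3, 5, 10, 20 cc) is the
  smallest sampled expansion with >= v cc of overlap. Thresholds are
  undefined (reported as None, never silently infinite) when the OAR is
  smaller than v cc, and may be negative for overlapping structures. An
  iterative morphological-dilation implementation is kept in the test
  suite as the independent oracle.
* **RNND**: both margins (face-neighbour surface voxels, world mm) are
  binned by planar azimuth about the superior-inferior axis; the default
  anatomical frame puts the origin at the duodenal-loop centroid with
  0 degrees toward the D1 centroid (the section adjacent to the stomach,
  which stays relatively fixed), so the profile spans 0-360 degrees
  around the C-loop. Per-bin nearest-neighbour distances are summarised
  by the mean and the 5th percentile (linear interpolation between order
  statistics); bins without partner points are flagged empty, not zero.
  Per-case profiles can be pooled after normalising each case by its own
  reference maximum.
* **Paired permutation test**: two-sided sign-flip test of the mean
  paired difference, p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm+1),
  default n_perm = 1000. All-zero differences give p = 1.

## Synthetic dosimetry

Plan optimization is out of scope; the dose stand-in preserves the one
property the analysis relies on: OAR dose is a monotone function of the
OAR-target geometry. With sd the (lightly smoothed) signed distance to
the PTV surface, dose = Rx at the surface, Rx·exp(-sd/falloff) outside
(falloff default 5 mm, chosen so the 0-4 mm anatomical gaps straddle the
V33Gy constraint), and a 10% interior hotspot ramp (fixed 5 mm scale)
inside. The ramp and the sub-voxel smoothing keep PTV V33Gy a
fine-grained function of the scale factor so every plan can be scaled,
by bisection, strictly into the 95% < PTV V33Gy < 96% comparability
band. Optional low-amplitude multiplicative noise emulates plan-to-plan
variability and is off in cohort runs (anatomy already varies).

The constraint set is the pancreatic SBRT protocol (33 Gy / 5 fx): PTV
coverage rules, <1 cc of duodenum/stomach/bowel at >= 33 Gy, <20 cc at
>= 20 Gy, plus kidney/liver/cord rules that are explicitly skipped when
those structures are absent (the phantom omits them). Comparators are
strict, exactly as printed in the protocol.

BED uses the linear-quadratic form n·d·(1 + d/(alpha/beta)) with
alpha/beta = 10 Gy for tumor. maxBED is the BED at the largest uniform
plan-scale factor violating no selected OAR constraint — variant
`duodenum_only` (P1 bookkeeping) or `all_proximal` (duodenum + stomach +
bowel). The search is bisection to 1e-4 on (0, 3.0]; the 3x cap is
reported when hit (well-separated anatomy), and constraints violated as
the scale approaches zero yield maxBED = 0 with an infeasibility flag.
Scaling acts on the per-fraction dose with the fraction number fixed.
Geometry-dose relationships are summarised by non-negative Gaussian fits
y = a·exp(-((x-b)/c)^2) (multi-start least squares; r^2 undefined for
degenerate responses).

## Decision support system

* **Limiting-OAR classes.** Given the required separation L1cc_TH:
  P1 — only the duodenal L1cc is below threshold; P2 — the duodenum and
  stomach and/or bowel; P3 — the duodenum is not below threshold. P3
  cases cannot benefit from a duodenal spacer (it spares only the
  duodenum), so their predicted gain is zero by construction.
* **Pre-injection maxBED network**: one hidden layer of 8 ReLU units on
  standardized (L1cc_duodenum, L1cc_stomach, L1cc_bowel), trained with
  L-BFGS to tolerance (deterministic under the seed; with cohorts of
  tens of cases a validation split for early stopping would starve
  training). Train/test RMSE on a seeded 70/30 split is reported.
* **Threshold model**: OLS of maxBED on the minimum OAR L1cc, inverted
  to L1cc_TH(desired BED); the threshold is carried as a Normal whose sd
  comes from the delta-method 95% inverse-prediction interval divided by
  1.96. A non-positive slope flags the model unusable.
* **Bayesian benefit model**: dmaxBED_Px = b0 + b1·X + b2·dL1cc_DUO +
  b3·X·dL1cc_DUO + eps with X = 0 for P1 and 1 for P2. Each simulated
  case contributes both targets: dmaxBED_P1 (post-spacer maxBED under
  duodenum-only constraints minus pre-injection maxBED) and dmaxBED_P2
  (same under all proximal constraints). Posterior sampling is a Gibbs
  sweep over the semiconjugate normal linear model — beta ~ N(0, 1e6 I),
  sigma^2 ~ Inv-Gamma(0.01, 0.01), alternating beta | sigma^2 and
  sigma^2 | beta — with 1,000 burn-in and 10,000 retained draws. In the
  diffuse-prior limit the posterior mean matches OLS, which is the test
  oracle; interval calibration is checked by simulation.
* **Prediction**: 10,000 joint samples of L1cc_TH (its Normal), a
  posterior (beta, sigma^2) draw and observation noise produce the
  dmaxBED posterior; the reported point estimate is the mode of a
  Gaussian-KDE (Silverman bandwidth) over those samples — the maximum
  likelihood estimate — alongside the mean and central 95% interval.
  The needed separation max(0, L1cc_TH - pre L1cc) is clamped at zero.
* **Placement recommendation** (an extension of the optimal-location
  output): the smallest scenario whose injected sections cover every
  duodenal interface section with section-level L1cc below threshold.

## Problem sizes and numerics

Default grids are 72^3 at 2 mm (the generator requires roughly a 64^3
grid at <= 2.2 mm to fit the anatomy); cohort studies run 20 cases x 4
scenarios with 6 insertion increments and ~4-5 mm tet edges, completing
in minutes on one core. Gibbs chains use 10,000 retained draws (2,000 in
repeated-calibration tests). Bisections run to 1e-4 (maxBED) or the
coverage band (plan scaling). Degenerate inputs fail loudly: empty masks,
empty boundary-condition sets (named in the error), oblique NIfTI
affines, unreachable coverage bands, rank-deficient regression designs
(collinear columns named), and spacer volumes that do not fit (the
achievable volume is reported).

## Known limitations

Linear elasticity with projection contact is the principal fidelity
simplification (no true frictional contact, no hyperelasticity); the
lumen filler is a surrogate for luminal contents; the dose stand-in has
no beam/arc structure, so absolute maxBED values are larger than
clinical plans would give and the escalation cap binds for
well-separated cases; and the cohort's geometry-dose relationship is
cleaner than patient data (no delineation noise), which flatters the
r^2 of the Gaussian fits. Conclusions supported by the tests are about
the pipeline's internal correctness and the direction and ordering of
scenario effects, not about clinical effect sizes.
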