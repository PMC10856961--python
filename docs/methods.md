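# Methods

This note records the models, numerical choices and known limitations behind
`bodyscan`. It is written for a maintainer or reviewer who wants to know *why*
the pipeline is built the way it is, not just what it does.

## The measurement model

The system estimates total body volume (BV) from exactly two depth/IR views of
a standing subject — one camera in front, one behind, each about 1.9 m away —
and converts volume to body composition through standard densitometry:

1. the body silhouette is detected in each IR image (threshold + region
   growth), fused with the depth image, and back-projected through the pinhole
   model to a world-frame point cloud;
2. the two clouds are registered (ICP) and meshed by Poisson surface
   reconstruction; the enclosed volume of the watertight mesh is the raw BV;
3. raw BV is mapped onto a reference scale (air-displacement plethysmography)
   by ordinary least squares — the "fitted" BV — and fat mass is predicted
   from sex, physical-activity minutes/week, height and fitted BV by a fixed
   linear equation (coefficients in `bodyscan.densitometry.FM_COEFFS`).

A two-view rig cannot observe lateral surfaces; the Poisson solve bridges
them. That in-fill is a *bias*, not noise, and it is deliberately left in the
raw volume: the linear calibration of step 3 absorbs it, which is the same
strategy the validation statistics are designed to test.

## Scene geometry and units

World frame: right-handed, +y up, origin at the centre of the standing
platform. Cameras sit at (0, 1.0, ±1.9) m with a horizontal gaze. An earlier
design aimed the cameras at the platform origin, but with Kinect-class
intrinsics (512×424 px, f = 365 px, ±30° vertical half-FOV) a camera tilted
27.8° down cannot keep a 1.75 m subject in frame at 1.9 m; horizontal gaze at
chest height is the configuration that actually frames an adult. Files store
depth in integer millimetres (uint16, 0 = invalid, z-depth along the optical
axis); geometry is computed in metres; volumes are reported in litres.

## Synthetic scenes

Phantoms are assemblies of solid primitives (sphere, capsule, ellipsoid,
cylinder, box) with analytic ray intersections, so every rendered depth pixel
has an exact geometric reference and the renderer can hand tests a pixel-exact
silhouette oracle. The `humanoid` preset (head, neck, torso, four limb
capsules, ~61 L) stands on the reflective platform; its limbs overlap the
torso so the outer surface is one shell, and the ground-truth volume of
overlapping assemblies is obtained by voxel counting (2 mm default; the
2 mm/1 mm discrepancy is below 0.2 %). Uniform scaling of a phantom scales the
reference volume exactly by the cube of the factor, which is how cohorts of
known volume are generated cheaply.

The IR model is two-level reflectance: background ~6, body ~200, platform
~245 (the "highly reflective paint"). This is sufficient for threshold-based
segmentation and is not a shading model. Depth noise is Gaussian per pixel
(mm) followed by random dropout to 0; rendering is a pure function of
(phantom, cameras, platform, seed).

What the synthetic scenes do **not** emulate: clothing and hair (the protocol
removes them), multi-path IR artifacts, pose variation, breathing motion, and
soft-tissue articulation. Passing tests therefore demonstrate the pipeline's
geometric correctness and its statistical machinery, not field performance on
real bodies.

## Segmentation

Otsu thresholding (policy-selectable to a fixed value) proposes foreground;
flood-fill region growth from the brightest *body* blob keeps one connected
component. Two platform-specific rules matter:

* seed selection ignores pixels at platform reflectance (≥ 235), so a large
  bright platform cannot out-vote a small body;
* `exclude_platform` removes mask regions contiguous with the bottom mask rows
  that are either platform-bright in IR or displaced from the silhouette's
  median depth by more than 150 mm. The IR cue is primary: the platform's top
  face is seen near-grazing and its depths overlap the legs', so depth alone
  cannot split them exactly.

Morphological cleanup is opening-then-closing with disk elements (the
open–close filter is idempotent, so re-cleaning is a no-op), then
keep-largest-component with a documented tie-break (equal sizes → smallest
row-major first-pixel index). On noiseless renders the final mask equals the
ray-cast silhouette pixel for pixel.

## Registration

`align_views` is trimmed point-to-point ICP: nearest-neighbour
correspondences, an absolute distance gate (default 15 mm, floored by the 5 %
distance quantile so badly initialised problems still converge), worst-10 %
trimming, closed-form Kabsch update.

Opposed two-view rigs add a subtlety that cost this project some analysis: the
only surface both cameras see is the visual rim, and perspective shifts each
view's rim curve toward its own camera by roughly r²/D (millimetres on limbs,
~15 mm on a torso). Nearest-neighbour correspondences therefore carry a
systematic "close the gap" signal along the camera baseline that is
indistinguishable from a true calibration error. Every unbiased-looking
variant we tried — distance gating, normal-compatibility gating,
rim-restricted correspondences, point-to-plane with a least-norm solve,
baseline-constrained motion models — re-routes the same bias through whichever
degree of freedom is left open and slowly collapses the body thickness (up to
tens of percent of volume). The resolution is a *calibration trust region*:
the pipeline accepts the ICP refinement only if the total correction stays
within the rig's pose uncertainty (defaults 10 mm / 1°); a converged
"correction" far beyond that, from a calibrated initialisation, can only be
rim-offset bias and is rejected in favour of the extrinsic alignment. With an
uncalibrated initialisation (the trust region disabled), ICP behaves as
normal and recovers constructed misalignments of 5° / 2 cm to better than
0.05° / 1 mm.

## Surface reconstruction and volume

Poisson reconstruction is implemented on a regular grid: outward-oriented
normals are splatted into a voxel vector field, and the indicator function is
recovered from `lap(chi) = -div(V)` with zero-Dirichlet boundaries via the
type-I discrete sine transform — an exact spectral solve of the 7-point
discretisation, deterministic and O(N log N). `poisson_depth` divides the
longest bounding-box axis into 2^depth cells (default 8, capped at 320 cells
per axis). The iso-level is the mean of the indicator sampled at the input
points; marching cubes extracts the surface, which is closed because the
iso-region stays interior to the padded grid.

Two numerical choices carry most of the accuracy:

* **normal orientation**: points from a depth view are oriented toward their
  recording camera — exact for 2.5D data — rather than away from the cloud
  centroid (which fails on limbs); the centroid rule plus a consistency sweep
  remains as a fallback for clouds without view provenance.
* **density-adaptive splatting**: each point's contribution is weighted by its
  squared local spacing (distance to the 8th neighbour), so sparsely sampled
  grazing regions contribute as much field per unit area as dense frontal
  ones. Without this the reconstructed surface sits ~1 cm inside the data in
  grazing directions and a body-sized sphere loses ~20 % of its volume; with
  it, two-view spheres recover volume to ~2 % and the humanoid to ~1 %.

Mesh volume is the signed tetrahedron sum over faces, |Σ det(v0,v1,v2)|/6,
and refuses to run on open or inconsistently wound meshes. Cleaning removes
small components, closes pinholes (general boundary-loop fan fill — trimesh's
`fill_holes` only handles triangle/quad holes), and smooths with Taubin
iterations followed by a uniform rescale about the centroid that restores the
pre-smoothing enclosed volume exactly, so smoothing never moves the volume
estimate.

Refinement behaviour: on a noiseless 10k-point sphere the volume error
decreases monotonically through depths 5–7 and plateaus at depth 8, where the
~0.8 mm grid outresolves the ~4 mm point spacing; the property test covers
the monotone regime.

Resolution matters through silhouette quantisation: each rim pixel ray can lie
up to half a pixel outside the true silhouette, adding a skin of roughly
(pixel footprint)/2 around the body — about +1 % volume at full 512×424
resolution, +6 % at half resolution. Accuracy tests run at full resolution;
orchestration tests that only exercise plumbing run scaled down.

## Densitometry and statistics

Replicate selection implements the closest-pair rule (agreement tolerance
150 mL or 0.3 % of the pair mean — the base of the percentage is a documented
choice); with three or more values the closest pair is always used, ties going
to the pair whose mean is nearest the overall median, then to the earliest
pair. Density is mass/volume; percent fat uses the two-compartment Siri
equation with the standard 495/450 constants (config-exposed). The thoracic
gas correction is consumed as an already-applied adjustment to reference BV;
its measurement is out of scope.

Agreement statistics use n−1 standard deviations throughout and a fixed 1.96
LoA multiplier. The Bland–Altman LoA confidence intervals use the standard
large-sample standard error SD·√(1/n + 1.96²/(2(n−1))) with t(n−1). ICC is
computed from the two-way ANOVA decomposition: ICC(2,1) (two-way random,
absolute agreement — the default, since both intra- and inter-observer
questions involve k-rater grids) and ICC(3,1) (consistency) with the standard
F-based confidence intervals; values match an independent sums-of-squares
oracle and `pingouin` to 1e-9 in tests. Best-subsets regression enumerates all
non-empty predictor subsets, reporting R², adjusted R² and Mallows'
Cp = RSS/MSE_full − n + 2(p+1); the full model satisfies Cp = p+1 identically.

## Synthetic cohort

`make_fixture_cohort` emulates a two-observer repeatability design (three
estimations per observer, six scan pairs per subject, camera pose jittered per
scan). Covariates are drawn once per subject: balanced sex, height
N(1.65, 0.08) m, weight N(67.5, 12.2) kg, age N(28, 6), ~45 % sedentary.
True BV is weight over a density drawn from N(1.035, 0.015) kg/L; the phantom
is the humanoid preset scaled uniformly to that volume. Reference replicates
add 0.05 L noise; reference fat mass is the prediction equation plus 1.4 kg
noise; the camera's raw BV column follows the generative rule
1.078·BV + N(0, 0.9 L) — a multiplicative overestimate of the kind lateral
in-fill produces, which the calibration regression must remove (and does, to
~0.1 % in the acceptance run). All randomness descends from the single cohort
seed.

## Known limitations

* The two-view geometry fundamentally under-constrains the lateral surface;
  bodies much thicker than ~0.5 m (or any convex body approaching the 1.9 m
  stand-off) lose volume to in-fill sag faster than calibration can be
  expected to fix.
* ICP along the camera baseline is only as good as the extrinsic calibration;
  the trust region protects against bias but also means a genuine baseline
  calibration error larger than the trust radius will not be corrected from
  the data.
* The IR model is two-level; segmentation on real IR imagery would need the
  threshold policy and the platform-reflectance constants re-tuned, or a
  learned segmenter.
* The fat-mass equation is an empirical cohort fit; the package applies it
  as given and warns, rather than fails, outside its covariate ranges.
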