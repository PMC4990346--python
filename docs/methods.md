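# Methods

## Vessel state model and tracking objective

A vessel is modelled as a discrete stochastic process over states
`V_i = [x_i, f_i, b_i, r_i]` sampled every S mm along the centerline: the
center follows the second-order recursion `x_i = 2x_{i-1} - x_{i-2} + eps_x`
(constant-velocity; a straight cylinder when unforced), the radius a random
walk, and the foreground/background intensity means second-order averages.
The driving noises are zero-mean Gaussians whose scales (`sigma_x`,
`sigma_r`, `sigma_f`, `sigma_b`) act as stiffness constants.  Curvature
regularization is implicit in the center recursion — three consecutive
points determine local curvature, and a small `sigma_x` prefers smooth
trajectories; torsion is deliberately not penalized.

Tracking is stepwise greedy MAP: M candidate points on the forward
hemisphere of radius S are each scored by the sum of the three squared
recursion residuals divided by their sigma values, plus an additive
contrast reward `-w (f - b)` clipped below at a floor.  Two conventions
deserve note:

* The residuals are divided by `sigma`, not `sigma^2`.  The sigmas are
  treated as variance-scale tuning constants with units absorbed into the
  configuration; only their ratios matter to the argmin.
* The contrast reward realizes the modelling assumption that lumen and
  background differ strongly in intensity.  The default weight
  `w = 1/300` makes a full lumen/myocardium contrast (~300 intensity
  units) worth the same as a 1.2-voxel geometric deviation, so geometry
  dominates unless a candidate is clearly inside bright tissue.  The floor
  (-3) stops a single very bright region from overwhelming the prior.

Greedy per-step minimization (rather than a multi-step path optimum) keeps
the tracker linear in track length; the active-search machinery recovers
the cases where a greedy step fails.

Defaults: `sigma_x = 0.5 mm`, `sigma_r = 0.2 mm`,
`sigma_f = sigma_b = 400`, `S = 1 mm`, `M = 192`, all config-exposed.

### Candidate lattice and determinism

Candidate directions come from a spherical Fibonacci lattice restricted to
the forward hemisphere (full 90-degree cap: the curvature penalty, not a
hard cone, discourages sharp turns).  Seed-direction initialization sweeps
a K = 512 full-sphere lattice, scoring each direction by the
Gaussian-weighted mean intensity in a cylinder of radius r0 and length 4S.
Nothing in the pipeline draws random numbers, so identical inputs and
configuration reproduce bit-identical trees, centerline files and meshes.

### Recentring and radius fitting

After each accepted step the point is pulled onto the local intensity
ridge: the intensity-weighted centroid (weights clipped at the f/b
midlevel) of a disc of radius 1.2 r in the normal plane, iterated twice
with the shift capped at 0.5 r.  This removes the lateral quantization of
the candidate lattice; on noise-free tubes the residual centerline error is
~0.05 mm (a tenth of a voxel).  The radius is then refit by scanning
r on a 0.1 mm grid in `[max(0.3, 0.5 r_prev), 2 r_prev]`, maximizing
disc-minus-annulus contrast in the normal plane penalized by
`(r - r_prev)^2 / sigma_r`.  Partial-volume halos bias the estimate
upward by roughly half a voxel; a flat contrast profile (no edge
information) returns `r_prev` unchanged.

## Planar vesselness and termination

The termination signal is the 2-D Hessian of the Gaussian-smoothed cross
section perpendicular to the track, evaluated at the center pixel with
analytic Gaussian-derivative kernels (scale `sigma = max(r/2, pixel)`,
half-extent 4r, pixel = min voxel spacing).  A bright elliptic lumen makes
the Hessian negative definite; the measure is

    v = sqrt(Ixx Iyy - Ixy^2)  if  Ixx + Iyy < 0  and  Ixx Iyy > Ixy^2
    v = 0                      otherwise,

a monotone function of exactly the trace and determinant, preferring
isotropic (disc-like) over elongated responses.  The kernels are DC-free,
so a constant section scores exactly zero, and the first-order intensity
term is deliberately ignored (pure second-order test).

A step whose best candidate scores `v` below a threshold is a *suspect*
step: the tracker then probes the straight-line prediction instead of
accepting the MAP candidate.  This blocks an end-of-vessel pathology —
near a terminus the in-lumen sideways candidates remain attractive and the
track would otherwise U-turn into already-tracked lumen — while still
crossing one- or two-step intensity dips natively.  Three consecutive
suspect steps terminate the track and the suspect states are trimmed.  The
threshold is `max(theta_abs, 0.1 x running median of the last 10 v)`; the
absolute floor (`theta_abs = 10`, intensity-scale dependent) exists because
a track seeded in pure background has a near-zero running median and a
purely relative rule could never fire.  The health check evaluates `v`
along the established forward direction, not the candidate's own direction:
a true continuation shows a bright disc there, while an oblique self-section
of tracked lumen does not.

## Branch detection

At each healthy step the high-posterior candidates are clustered
(single linkage, linking distance `S_det sin(15 deg)`); at least two
clusters of >= 3 members whose centroids separate by more than `0.7 S_det`
signal a bifurcation; one event per non-principal cluster (so
multifurcations emit several).  Candidates enter clustering when they are
in the best 25% by cost *and* within an absolute cost window (50) of the
best candidate — the quantile alone would pad the selection with junk that
forms fake lobes.

Detection uses its own hemisphere of radius `S_det = 2S` with a probe
sphere of radius r/2.  This is a geometric necessity, not a tuning choice:
with the tracking hemisphere radius equal to the step and to the typical
parent radius, *every* candidate lies inside the parent lumen (lateral
offset `S sin(theta) <= r` for all theta), so the high-posterior set is
always one connected cap and no clustering rule can split it.  At 2S, off-
axis candidates clear the wall, the small probe sphere makes them fail the
foreground model hard, and a daughter appears as a genuinely separated
lobe.  A candidate lobe nearly collinear with the forward direction
(< 25 degrees) is rejected as the parent itself.

Clustering fires only once the tracker's center has passed the junction
far enough for the daughter lobe to clear the wall at the detection shell,
so the raw event point lags the true bifurcation by one to several steps.
Once the daughter has been tracked, the event is relocated to the parent
point nearest the daughter's own axis (a PCA line fit over daughter states
3-8, skipping the first two while the track converges onto the true axis);
the refinement is accepted only when the axis passes within 1 mm of the
parent.  This reduces the localization error from the lag scale (1-4 mm)
to the tracking-error scale (~0.15 mm) and applies to branches recovered
by the type-2 search as well.

Daughter seeds spawn one step along the daughter direction.  They are
deliberately exempt from the "near already-tracked lumen" veto (they always
start near their parent); a false daughter pointing back into tracked
vessel dies within a few steps via the self-intersection guard and is then
removed as a duplicate at assembly.  Dip-statistic multimodality testing
and k-means daughter refinement are not used.

## Active search

Three exhaustive local searches recover what sequential tracking loses:

* **Type 1 (disconnected vessel).**  A track that terminated with healthy
  recent vesselness (mean of the last 5 points >= 3x the termination
  threshold) and healthy radius (>= 0.5x the running median) ended
  *abruptly* — the signature of an intensity gap, not a real terminus.
  The forward cone (`dist(s, x_i) <= T_th = 6 mm`, angle <= 60 degrees,
  grid 0.5 mm) is probed; points must beat the local foreground estimate
  minus one noise sigma and show positive planar vesselness along `s - x_i`.
  Survivors closer than 1 mm merge; tracking resumes from the *nearest*
  surviving probe (so that the interpolated gap states stay inside the true
  gap) and the pieces are spliced with straight interpolated states flagged
  `bridged`.  The printed forward constraint is implemented as an angle
  bound: a raw upper bound on an unnormalized dot product would exclude
  forward points and admit backward ones.
* **Type 2 (disconnected branch).**  At each state without a nearby branch
  event, above-threshold voxels in the shell `r_i..3r_i` (current lumen
  removed) are 26-connectivity labelled; a blob of >= 5 voxels triggers the
  cone search with the cone relaxed to 90 degrees.  Resulting seeds within
  2 local radii of any tracked center are dropped; the rest are ordered by
  planar vesselness (strongest evidence first, so a clean in-lumen seed is
  tracked before a marginal junction-wedge seed can occupy the territory),
  tracked, and judged at assembly (false positives are deleted there).
  An active-search seed lands mid-vessel, so it is tracked in both
  directions and the halves are joined into one centerline — forward-only
  tracking would lose the proximal part of a recovered daughter.
* **Type 3 (branch-occurrence model).**  The distance from the ostium to
  the first left-main bifurcation is modelled as Poisson
  (`P(x) = e^{-lambda} lambda^x / x!`, x binned to integer mm).  The ML fit
  over the eight packaged training distances gives
  `lambda_hat = 17.3325 mm`.  A left-tree track that passes the 0.9
  quantile (23 mm) without any branch triggers a proximal re-run of the
  type-2 search over the first 30 mm with the intensity rule relaxed to
  two sigmas; the monitor is inert once any branch is recorded.

## Tree assembly, pruning, export

Segments link to parents through their branch events.  Pruning iterates to
a fixpoint: (a) segments shorter than 3 mm; (b) segments whose mean planar
vesselness is below 25% of the per-point median of the longest root
segment — tracks that wandered into a bright decoy blob score ~20% of the
root level while true daughters score ~85%, so the band is wide on both
sides; (c) duplicates (>= 50% of points within one local radius of another
retained segment), keeping the longer.  Children of a pruned segment fall
with it; an edge that would close a cycle is dropped with a warning.

Centerlines export as one `x y z r` text file per root-to-leaf path —
every segment's distal end is a leaf, since a parent keeps running past
the bifurcations attached along it — plus a JSON document with segments,
edges, branch events, bridged flags and the pruning audit trail.  The
lumen mesh is a generalized tube per segment: 16-vertex rings of the
stored per-point radius on rotation-minimizing frames (double-reflection),
capped ends, daughter rings within one parent radius of the attachment
omitted; no junction blending or gradient-based surface refinement.

## Synthetic phantoms

The phantom module rasterizes declarative tube-tree specs: cubic-spline
centerlines (dense 0.05 mm discretisation), per-arc radius profiles,
stenosis intervals (radius scale), gap intervals (foreground suppressed,
truth centerline continuous), decoy spheres, and additive Gaussian noise
from a seeded generator.  A voxel is foreground when its center is within
the local radius of the nearest centerline sample — which also rounds the
tube ends into spherical caps.  Defaults: 128^3 grid at 0.5 mm isotropic,
foreground 350, background 50, noise sigma 20, chosen to mimic the
contrast scale of an enhanced lumen against myocardium at clinical CT
resolution.  The standard suite covers a straight tube, a C-shaped arc
(curvature radius 20x tube radius), a 45-degree bifurcation (parent radius
1.0 mm, daughter 0.8 mm), a 3 mm mid-vessel gap, a daughter detached by a
2 mm gap, a 40% focal stenosis over 5 mm, and a decoy blob 1 mm off the
vessel wall.

What the phantoms do *not* emulate: curved/moving anatomy, beam hardening,
streak artifacts, spatially correlated noise, intensity inhomogeneity
along the vessel, and elliptic or irregular lumen cross sections.  Passing
the suite therefore demonstrates the mechanisms (recovery of gaps,
branches, decoy rejection) under controlled conditions, not clinical-grade
accuracy; on real CCTA the same thresholds would need recalibration to the
scanner's intensity scale.

## Evaluation

The overlap metrics are simplified analogues of the challenge-framework
scores, defined on nearest-point matching: a reference point is covered
when its nearest candidate point lies within the reference radius;
OV = covered fraction, OF = covered prefix fraction from the reference
start, OT = OV over points with radius >= 0.75 mm (the "clinically
relevant" stand-in), AI = mean matched distance over covered points.  They
preserve the intent of the official definitions but are not the official
scoring, which requires annotated clinical correspondence.

The planar measure is validated against an independent 3-D multiscale
tube filter (scikit-image's Frangi implementation, scales 0.5/1.0/1.5 mm)
sampled along phantom centerlines extended 5 mm past the distal end; both
profiles are high on-vessel and near zero beyond it, and correlate at
r ~ 0.9 (the acceptance floor is 0.7).

## Problem sizes and numerical choices

Tests and the acceptance script run the full suite at 128^3 / 0.5 mm with
~50-state tracks; one tree extraction takes a few seconds on one core.
Ties in the direction sweep break to the smallest lattice index; the
radius scan grid is 0.1 mm; out-of-bounds samples return the global
volume minimum and set a flag rather than erroring, because the tracker
probes freely near volume edges.  Non-axis-aligned volume orientations are
rejected on read rather than silently resampled.

## Known limitations

* Stepwise greedy MAP can commit to the wrong candidate where a path-level
  optimum would not; the active searches mitigate but do not eliminate
  this.
* The radius estimate carries a positive partial-volume bias of about half
  a voxel and is bounded to `[0.5, 2] x` the previous radius per step, so
  abrupt caliber changes lag by a few states.
* `theta_abs`, the intensity thresholds and the contrast weight are
  intensity-scale dependent (tuned to the phantom's ~300-unit contrast);
  volumes on other scales need the config adjusted.
* Branch detection assumes daughters depart at >= 25 degrees; a nearly
  tangential daughter is invisible to clustering (though type 2 usually
  recovers it).
* The Poisson branch model covers only the first left-main bifurcation.
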