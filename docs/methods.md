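# Methods

This note records the models, numerical choices and known limitations of
`subshape`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Conformal surface representation

A subcortical structure is modelled as a closed genus-zero, tube-like
triangle mesh in a common millimetre frame.  The parameterization maps
it to the rectangle `u ∈ [0, 1]`, `v ∈ [0, 2π)` (v periodic):

* **Cut selection.** The two cut points are the extremal vertices along
  the first principal axis of the vertex cloud.  This is deterministic
  and reproducible; for elongated structures the principal axis is
  stable under the smooth shape variation the generator produces.
* **Axial coordinate.** `u` solves the discrete Laplace equation
  (cotangent weights) with the cuts pinned to 0 and 1.  A point
  Dirichlet condition makes the raw harmonic coordinate crowd
  logarithmically near the poles, so `u` is relabelled by the surface
  area CDF: level sets are unchanged, but grid rows become equal-area.
  Injectivity is checked on the raw coordinate (the relabelling is
  monotone); flipped parameter triangles beyond a 0.2 % allowance raise
  an error with the flip count.
* **Angular coordinate.** The mesh is cut along the shortest edge path
  between the poles (Dijkstra); interior seam vertices are duplicated
  and `v` solves Laplace with 0 on one seam copy and 2π on the other.
  The two pole vertices and their incident faces are excluded (the
  coordinate is singular there); natural boundary conditions apply at
  the polar holes.
* **Resampling.** Grid nodes sample `u` at cell centres
  `(i + ½)/nu` — the poles themselves are parameterization
  singularities — and `v` at `2πj/nv`.  Positions and curvature are
  interpolated barycentrically in the parameter domain (KD-tree point
  location over a 3-fold v-tiling); queries just outside the
  triangulated band extrapolate linearly from the nearest triangle,
  which keeps the end rows non-degenerate.  Isolated nodes where the
  finite-difference area density still vanishes (parallel tangents at
  an end row) are repaired from their ring neighbours and counted in
  the grid metadata; more than 1 % such nodes is an error.
* **Channels.** The conformal factor is defined as the area-distortion
  density `λ = |X_u × X_v|` (surface area per unit parameter area), so
  `Σ λ Δu Δv` reproduces the surface area; the tests require agreement
  within ~1 % on the synthetic templates.  Mean curvature uses the
  cotangent-Laplacian mean-curvature normal with mixed Voronoi areas,
  signed positive for a sphere with outward normals; vertices touching
  triangles with a minimum angle below 0.5° are flagged and replaced by
  their one-ring average.  For parametric grids an equivalent
  finite-difference formula (first/second fundamental forms) is used;
  its two rows nearest each pole carry one-sided-stencil error and are
  treated as such in tests.
* **Default resolution.** 100 × 150 = 15,000 grid vertices; `u` (along
  the medial axis) gets the smaller dimension because the structures
  are longer than they are round.  Tests and the acceptance experiments
  run at 30 × 40 to keep the suite fast; every contract checked is
  resolution-independent.

Registration consumes the two channels standardized to zero mean / unit
variance over the grid (the affine parameters are kept in metadata, so
the transform is invertible).

## Fluid registration by mutual information

Registration estimates a parameter-domain displacement `d(x)` such that
`subject(x + d(x)) ≈ template(x)`, by maximizing the sum of the two
channels' mutual information.  The force at each node is the classic
likelihood-ratio MI gradient: the derivative of
`log p(a,b)/(p(a)p(b))` with respect to the moving intensity, evaluated
at the sample's joint-histogram position, times the warped moving
image's spatial gradient.  The velocity is the force smoothed by a
Gaussian of width `sigma_fluid` — the standard fluid approximation to
the viscous PDE solve.  Integration is explicit Euler with an
accept/reject line search (a step is accepted only if MI strictly
improves; rejections halve the step and eventually stall to
convergence), on a coarse-to-fine pyramid, with regridding (compose and
reset) whenever min det J drops below `regrid_threshold`, at any level.
The v axis is periodic throughout; the u boundary rows carry zero
axial displacement (cut points correspond by construction).

Defaults: `bins=64`, `sigma_fluid=2.0` cells, `levels=3`,
`max_iter=200` per level, `regrid_threshold=0.5`, `tol=1e-5`.  64
partial-volume bins noticeably sharpen warp recovery on these smooth
synthetic images relative to coarser histograms; all knobs are exposed
in `RegistrationParams`.

Numerical caveats worth knowing:

* Partial-volume binning makes MI non-stationary at grid-aligned
  identity (a known PV artifact).  Exactly identical inputs therefore
  short-circuit to the zero field; near-identical inputs may acquire a
  few hundredths of a cell of drift.
* Composition of regridded increments can graze det J ≤ 0; a light
  Gaussian smoothing of the total field (recorded in the metadata) is
  applied progressively until the map is diffeomorphic again, and an
  error is raised if that fails.
* The recovery contract (mean endpoint error < 0.5 cells for smooth
  warps up to ~3 cells) is met for warps whose own Jacobian stays
  comfortably positive; a warp that nearly folds is not a fair
  recovery target at this resolution.

## Morphometry features

* `RD(u, v)`: Euclidean distance from the node to the centroid of its
  iso-parametric ring.  On tube grids the ring centroid estimates the
  medial axis and the ring is perpendicular to it by construction.
  Note the medial axis is estimated per subject: a radial deformation
  confined to part of a ring moves that ring's centroid slightly, so a
  partial-ring offset of δ changes RD by slightly less than δ (exactly
  δ holds against the template's centroid, which is what the
  noise-free generator test asserts).
* `TBM = det J` directly (not log det J), with an error if any
  determinant is non-positive.
* `mTBM = (L₁₁, √2·L₁₂, L₂₂)` with `L = log(J Jᵀ)` via
  eigendecomposition.  The √2 on the off-diagonal makes the Euclidean
  norm of the 3-vector equal the Frobenius norm of L, i.e. vector
  distances realize the Log-Euclidean metric.
* `MMS` is the exact concatenation `(RD, mTBM)`; the container verifies
  this bitwise.

Features are indexed to template nodes: RD is computed on the subject's
own grid and pulled back through the registration correspondence; TBM
and mTBM come from the registration Jacobian at the template node.

## Permutation inference

Group labels are shuffled as whole label vectors — one shared shuffle
per permutation across all vertices — preserving the spatial dependence
of the maps.  Vertex p-values compare `|t|` for t statistics (two-sided;
the sign convention is group 1 = reference minus group 2) and the raw
value for T² (inherently one-sided); both are exact multiples of
`1/n_perm`.  Hotelling's T² adds a ridge of `1e-8·trace(S)/d` only when
the pooled covariance is numerically singular, so the regular case is
exact to machine precision (verified against dense-algebra oracles).

The corrected global p uses the count statistic: the observed "real
effect" is the number of vertices with uncorrected p < α; each
permutation's map is converted to a p-map against the permutation
distribution itself (leave-self-in ranks; the alternative leave-self-out
convention differs by O(1/n_perm)) and its count compared.  Ties count
as "at least as extreme", favouring significance; a global p of zero is
reported as `< 1/n_perm`.  A consequence worth noting: an implanted
effect only drives the global p down when its significant-vertex count
exceeds the null expectation of about `α · n_vertices`, so small regions
can be locally obvious yet globally non-significant — the same
global/local dissociation that motivates reporting both.

Direction maps follow the reference-minus-affected sign convention:
mean(group 1) − mean(group 2) > 0 at a significant vertex means the
affected group's value is reduced (atrophy), < 0 expansion.  Clinical
correlation maps use Pearson's r with the two-sided parametric p and an
uncorrected α, matching the analysis style of the statistics stage.

## Sparse coding and classification

Patch layout: corners uniform over valid positions, v windows may wrap;
the layout is sampled once per experiment and shared by all subjects.
Default 1008 windows; the patch-size sweep (20→30 in steps of 5) is a
config loop.

Stochastic Coordinate Coding streams over shuffled samples: a few
coordinate-descent cycles update the code (warm-started across epochs),
a stochastic gradient step updates only the active dictionary columns
with per-atom `1/√count` learning rates, and updated columns are
renormalized.  Atoms are initialized from random data samples (standard
dictionary-learning practice; a pure random-Gaussian init leaves
`|Dᵀx|` below any useful sparsity threshold on these data).  The
held-out LASSO objective is tracked per epoch.  Encoding solves the
full LASSO per patch by cyclic coordinate descent with an active-set
speedup (full sweep every tenth pass) to a 1e-6 relative objective
tolerance; it is verified against an independent proximal-gradient
solver.  Defaults `k=256` atoms, `γ=0.15`, 10 epochs at full scale;
the desk-scale experiments use `k=48`, 3 epochs on 120 patches of side
10 at 30 × 40 grid resolution.

Inside cross-validation the patches are scaled by the median training
patch norm (so γ acts on an O(1) scale) and the dictionary is re-learned
on training folds only — no information from test subjects reaches the
encoder.  Subject vectors are the 2×2/stride-2 max-pooled code matrix,
flattened (the alternative global per-atom max is available and recorded
in the report).  GentleBoost fits, per round, a depth-≤3 regression tree
minimizing weighted squared error, adds it to the ensemble, and updates
`w ← w·exp(−y f(x))`, renormalized; 100 rounds by default (60 in the
desk-scale experiments).  Fold allocation is random and unstratified
(n=311 at 10 folds gives nine folds of 31 and one of 32); fold metrics
with empty denominators are reported NA and excluded from the mean with
a warning.  Class imbalance is deliberately not corrected.

## The synthetic cohort generator

The generator emulates the product of a segmentation + reconstruction
pipeline: smooth genus-zero surfaces in a common frame with localized
group effects.

* **Templates.** `hippocampus_like`: an elliptical tube (radius ≈ 4–6 mm,
  section ratio 0.75) swept along a 110° circular arc of radius 20 mm —
  a banana.  `amygdala_like`: a smoothed superellipsoid with semi-axes
  (10, 8, 7) mm, exponent 0.8.  A seeded low-order harmonic radius
  texture (~6 %) gives each template the curvature landmarks that
  intensity-driven registration needs.
* **Shape noise.** Per subject, a radial offset field from harmonics of
  band ≤ 8 in u and v (periodic in v), normalized to exactly the
  configured RMS (default 0.3 mm — a plausible scale for segmentation
  and reconstruction variability at 1 mm MRI resolution).
* **Effects.** Rectangular parameter regions with a raised-cosine edge
  falloff (25 % of the extent), applied along outward radial directions;
  atrophy is inward.  The first-listed group is the reference and is
  never deformed.  Magnitudes of 0.3–1.5 mm are recovery-test scales,
  chosen to bracket the noise, not to mimic disease effect sizes.  The
  generator rejects offsets that exceed the local template radius
  anywhere inside the region (self-intersection guard).
* **Tangential misalignment.** Optional per-subject smooth
  parameter-domain jitter (bands ≤ 2, u component tapered to zero at the
  cuts) emulates the indexing disagreement that independent per-subject
  parameterization produces; it is what registration genuinely has to
  undo.  Off by default, since the upstream protocol this emulates
  pre-aligns scans rigidly.
* **Scores.** Each synthetic clinical score is Normal(mean, sd) with a
  configured correlation ρ to the subject's realized mean deformation
  inside the effect regions, constructed from the standardized latent
  deformation plus independent noise.
* **Ground truth.** Region masks (seed-independent), the signed radial
  offset field, labels and the score table (including the latent
  deformation column) are returned and serialized (JSON with
  run-length-encoded masks, TSV scores, PLY meshes).

What the generator does **not** emulate: anatomical subfield geometry,
segmentation topology errors, MRI intensity artifacts, rigid/scale
misalignment (an option exists but is off by default), or realistic
disease effect magnitudes.  Passing recovery tests therefore demonstrate
that the pipeline's statistics and machinery behave correctly under
controlled shape change — not that the method would attain any
particular sensitivity on clinical data.

## The recovery experiments

The radial-atrophy recovery experiment (2 × 20 subjects, 30 × 40 grid,
noise 0.2 mm, δ = 3× noise over a region covering ~22 % of the grid)
evaluates RD on the generator's common grid indexing, where
correspondence is exact by construction; registration accuracy is
validated separately by the known-warp experiment.  The reason for this
separation is a genuine property of the method observed at desk scale:
an MI-driven registration flexible enough to undo tangential
misalignment can also partially "explain away" a radial group
difference by warping the affected region's (λ, H) pattern toward the
template, moving signal from RD into the Jacobian channel in a
noise-dependent way.  At clinical scale this trade-off is settled by
strong regularization and large n; at 1,200 vertices and 40 subjects it
makes registration-pulled-back RD recovery unstable across seeds, so
the two capabilities are tested where each is identifiable.

The classification experiment uses a strongly separable cohort
(δ = 1.0 mm over 0.2 mm noise, so the Bayes accuracy is essentially 1)
and the full patch → SCC → pooling → GentleBoost chain with per-fold
dictionaries; a label-shuffle control verifies the chain cannot
manufacture accuracy from noise.

## Numerical conventions and degenerate inputs

* Grid indices 0-based; u index slowest; v half-open periodic.
  Displacements are stored in grid-cell units (a parameter-unit view is
  provided); Jacobians are dimensionless with unit cell spacing.
* Duplicate-vertex merge tolerance on mesh read: 1e-9 mm; winding is
  made consistent and oriented outward (positive volume).
* Simplification preserves manifoldness and genus via the edge link
  condition; when no legal collapse remains it stops early and reports
  the achieved face count.
* Zero pooled variance at a vertex yields t = 0 with a flag; both-group
  constant multivariate data yield T² = 0 with a flag; an exactly zero
  mean difference at a significant vertex leaves the direction label
  empty with a warning.
* `n_perm` exceeding the number of distinct group splits warns and
  proceeds with sampled permutations.
* All randomness flows through named integer seeds (simulation,
  patches, dictionary, folds, permutations); identical configuration
  and seeds reproduce results bit-for-bit on one platform.

## Known limitations

* The parameterization targets tube-like genus-zero surfaces; highly
  branched or flat structures would need a different cut strategy.
* The conformal factor is a discrete area-density surrogate; no claim
  of exact discrete conformality is made, and the quasi-conformal error
  grows at the polar rows.
* The MI estimator uses hard-binned plug-in entropy for the scalar MI
  function and partial-volume binning inside registration; both are
  biased for small images, which is acceptable for ascent but not for
  absolute MI values.
* GentleBoost weak learners come from scikit-learn's regression trees;
  exact tree structure (and hence per-fold metrics) can shift across
  scikit-learn versions even at fixed seeds.
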