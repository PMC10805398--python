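# subshape

Surface-based morphometry (SBM) of small subcortical structures — the
hippocampus and amygdala — as used to characterize shape change in
Parkinson's disease cognitive subtypes.  Where volumetry reduces a
structure to one number, SBM tests every vertex of a reconstructed
surface, resolving patterns in which atrophy and expansion coexist
within one structure and would cancel in a volume comparison.

The package implements the complete analysis chain as a reusable,
tested library, exercised end-to-end on synthetic cohorts with known
ground truth:

1. **Surface core** — closed genus-zero triangle meshes (PLY / legacy
   VTK), quadric edge-collapse simplification, Loop subdivision,
   cotangent mean curvature, and a conformal parameterization that maps
   each tube-like surface onto a fixed `(u, v)` grid (default
   100 × 150 = 15,000 indexed vertices).  Each grid node carries the
   conformal factor λ (area-distortion density) and mean curvature H;
   the pair (λ, H) determines the surface up to rigid motion.
2. **Fluid registration** — each subject's (λ, H) image pair is
   registered to a template's by a viscous-fluid flow that ascends the
   summed mutual information (MI), yielding a diffeomorphic
   parameter-domain deformation and its per-node Jacobians J.
3. **Morphometry** — per-vertex features:
   radial distance `RD` (distance to the medial-axis point of the
   vertex's iso-parametric ring, a thickness surrogate),
   `TBM = det J` (tangential area change),
   `mTBM = vec log(J Jᵀ)` (the 3-component Log-Euclidean deformation
   tensor), and the 4-vector `MMS = (RD, mTBM)`.
4. **Vertex statistics** — two-sample t (RD, TBM) or Hotelling's T²
   (mTBM, MMS) per vertex; inference by label permutation with one
   shared shuffle per permutation; multiple-comparison correction by
   the count statistic: the global p is the fraction of permutations
   whose count of significant vertices exceeds the observed "real
   effect".  Direction maps label significant vertices atrophy /
   expansion from the sign of the group mean difference; Pearson maps
   relate features to clinical scores.
5. **Sparse-coding classification** — 1008 random square patches
   (20×20–30×30 vertices) of the MMS maps, sparse-coded against an
   over-complete dictionary learned by Stochastic Coordinate Coding,
   2×2/stride-2 max pooling, and a GentleBoost ensemble of regression
   trees, evaluated by 10-fold cross-validation with ACC / SEN / SPE /
   PPV / NPV.
6. **Synthetic cohorts** — analytic hippocampus-like (banana tube) and
   amygdala-like (superellipsoid) templates; per-subject smooth radial
   noise, optional parameter-domain jitter, group-localized radial
   atrophy/expansion of known magnitude and location, and synthetic
   clinical scores with a configured correlation to the realized
   deformation.  Every generated quantity is returned as ground truth
   so the pipeline can be validated as a recovery experiment.

## Worked example

Simulate a two-group cohort (20 HC vs 20 PD-like subjects, 30×40 grid)
with 0.6 mm of radial atrophy implanted in a known region over 0.2 mm of
smooth shape noise, then test for it:

```python
import numpy as np
from subshape import (SimulationConfig, EffectRegion, simulate_cohort,
                      CohortFeatures, permutation_test, direction_map)
from subshape.morphometry import radial_distance

cfg = SimulationConfig(
    structure_kind="hippocampus_like",
    n_per_group={"HC": 20, "PD": 20},
    grid_dims=(30, 40),
    noise_sd=0.2,                      # mm, smooth per-subject shape noise
    effect_regions=[EffectRegion(u_range=(0.25, 0.75), v_range=(0.5, 3.5),
                                 delta=0.6, direction="atrophy")],
    seed=3)
meshes, truth, grids = simulate_cohort(cfg, return_grids=True)

rd = np.stack([radial_distance(g).ravel() for g in grids])[:, :, None]
cohort = CohortFeatures(rd, np.array(truth.subject_labels), "RD")
stat_map = permutation_test(cohort, n_perm=1000, alpha=0.05, seed=7)
directions = direction_map(cohort, stat_map)

mask = truth.combined_mask.ravel()
dice = 2 * (stat_map.sig_mask & mask).sum() / (stat_map.sig_mask.sum() + mask.sum())
print(f"significant vertices : {stat_map.real_effect} / {cohort.data.shape[1]}")
print(f"global corrected p   : {stat_map.p_global_label}")
print(f"Dice(sig, truth)     : {dice:.3f}")
print(f"atrophy vertices     : {(directions.labels == 1).sum()}")
print(f"expansion vertices   : {(directions.labels == -1).sum()}")
```

Output:

```
significant vertices : 375 / 1200
global corrected p   : 0.015
Dice(sig, truth)     : 0.587
atrophy vertices     : 358
expansion vertices   : 17
```

375 of 1,200 vertices exceed the uncorrected 0.05 threshold — far more
than the ~60 expected under the null — and only 15 of 1,000 label
shuffles produce as many, giving a corrected global p of 0.015.  The
significant set overlaps the implanted region (Dice 0.59; the implanted
raised-cosine falloff band is only partially detectable, which bounds
the achievable overlap), and nearly all significant vertices are
labelled atrophy, matching the implanted direction.

A command-line interface mirrors the library
(`subshape simulate / parameterize / register / stats / classify / run /
report`); `subshape run --config cfg.json` executes the full staged
pipeline with a resumable manifest.

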