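# Methods

## Transform model

All transforms act on world-space millimetre coordinates and map
reference-space coordinates to moving-space coordinates (backward mapping;
resampling pulls each output voxel's value through the transform). The
anisotropic similarity is the affine `A = R·diag(S)·Uᵀ` with the scaling
frame `U` fixed. Conventions chosen where the factorization is ambiguous:

* `decompose_affine` returns SVD-ordered (descending) scalings with
  `det R = det U = +1`; reflections (`det A ≤ 0`) are rejected outright —
  they cannot occur in brain registration and would force a negative
  scaling. When a caller owns the frame, `decompose_with_frame` reports the
  scalings in the caller's column order and never reorders `U`.
* Quaternions are real-part-first; `q` and `−q` encode the same rotation,
  canonicalized so the first component of magnitude > 1e-9 is positive.
* With `y = x` the factorization forces `R = U` (not `R = I`): the identity
  matrix written in frame form is `U·I·Uᵀ`.

## Point-set estimation

The alternating scheme updates the rotation (smallest-eigenvalue
eigenvector of the 4×4 quadratic-form matrix `B`) and the scalings (exact
1-D minimizers) in that order within each sweep; both steps solve their
sub-problem exactly, so the weighted cost is non-increasing across sweeps.
Choices the derivation leaves open:

* **Initialization.** Two warm starts are run by default — identity scaling
  with the rigid-fit quaternion, and the closed-form similarity fit
  re-expressed in the frame (`s·R_sim = (R_sim U)·(sI)·Uᵀ`) — and the
  lower-cost run is returned. The second start guarantees the anisotropic
  fit never ends above the similarity fit, which the class nesting
  (rigid ⊂ similarity ⊂ anisotropic similarity ⊂ affine) demands; a single
  start can stall in a local minimum above it. Supplying `S_init` forces a
  single run from that scaling.
* **Stopping.** Relative cost change < 1e-8 (default) or 100 sweeps,
  plus an absolute floor of 1e-17 × the initial cost so noiseless problems
  do not churn at rounding level.
* **Eigenvalue ties.** If `B`'s two smallest eigenvalues differ by less
  than 1e-10·‖B‖ the eigenvector closest (by |dot|) to the previous
  iterate is taken, for continuity across sweeps.
* **Scaling derivatives.** `∂P_ξ/∂s_j` follows from linearity of the
  matricial quaternion in its argument: it is `P` of the pure quaternion
  `x̃_j e_j`. The matrices are locked against central finite differences in
  the test suite (to 1e-6), and `Q_{y′}∂P_ξ/∂s_j` is verified symmetric.
* **Weights** multiply each point's term everywhere: barycenters, `B`, the
  scaling sums and the reported cost. Duplicating a point with half
  weights is exactly equivalent to the single point.

Degenerate inputs raise typed errors: coplanar points for the affine fit,
collinear points for rigid/similarity, zero weighted spread along a frame
column (named in the error), and non-positive scaling estimates.

## Block-matching registration

Per pyramid level (default ×4/×2/×1, levels too coarse to host a block plus
its search window are skipped), iterations alternate:

1. the moving image is resampled through the current transform and each
   reference block (5³ voxels, lattice step 2, top 75% by intensity
   variance inside the mask) is matched by exhaustive integer-offset search
   (radius 3) under the squared Pearson correlation;
2. matched positions are mapped back through the current transform and the
   requested fitter is run on the absolute world-mm pairs with scores as
   weights, directly yielding the updated *total* transform.

Matching in resampled space is essential: comparing fixed-size blocks
across a 25% stretch biases the correlation peak and the recovered scalings
by several percent; after resampling the residual is near-identity and the
bias vanishes. Fitting total transforms (rather than composing increments)
keeps the anisotropic-similarity class closed during aggregation and makes
"refit the final match set" reproduce the final transform exactly.

Further choices: the moving image is zero-padded by (block half-width +
search radius) so border blocks stay usable; registration starts from the
intensity-centroid translation unless an initial transform is given;
iterations stop early when the update moves block centers by less than
0.01 voxel; pairs with best score below 0.05, or with flat blocks, are
dropped; the mask restricts reference block extraction only. Everything is
deterministic — the config seed is recorded but no randomness is consumed.

The two-step ROI protocol estimates a whole-image affine, projects it to
the nearest similarity (mean singular value; translation from the matched
barycenters), then runs the ROI-masked anisotropic registration initialized
there. Because a similarity composed with an anisotropic similarity of
frame `U` stays in the class of `U`, the result's scalings are directly the
per-direction factors.

## Scaling directions

The first direction is the mid-sagittal plane normal, estimated by rigidly
registering the image onto its left-right mirror and reading the reflection
`S = F ∘ T` off the result (normal from the dominant eigendirection of
`(I − L)/2`, plane point from the midpoint of a point and its image). The
estimate is refined over three sweeps, re-mirroring about the current
plane so the residual rotation the matcher must capture shrinks each time.
This is a symmetry-registration substitute for dedicated mid-sagittal
detectors; when the symmetry map is far from a reflection or the match
scores are poor (mean < 0.4, e.g. on an asymmetric image) it falls back to
the grid mid-plane with a logged warning.

Directions two and three are the leading and secondary eigenvectors of the
covariance of the nonzero-voxel world coordinates (unweighted — voxel
membership, not intensity) projected onto the plane. Signs are fixed
(column 1 toward +x, column 2 toward +y, column 3 flipped if needed for
`det U = +1`) so factors are comparable across runs. A relative in-plane
eigenvalue gap below 1e-9 (a sphere) raises an ambiguous-frame error. One
frame is computed from the whole-brain mask and shared by all ROIs by
default; callers may compute per-ROI frames.

## Growth analysis

Relative factors are divided by the baseline (neonate) group mean per
(ROI, direction, reference); the baseline mean is exactly 1 afterwards, and
the operation is idempotent. Sex-balance weights use a 2-year window
centered on each subject's age: a female is weighted by the male fraction
in her window and vice versa; single-sex windows produce zero weights
(warned, and such weights simply remove those points from the fit).

The four candidate families are fitted by bounded trust-region least
squares from 10 starts (asymptote ≈ max(y), rates {0.1, 0.5, 1, 2}, seeded
jitter); rates are kept positive, which also keeps the rational pole
`x = −c` outside the nonnegative age range. The Gaussian log-likelihood
uses the maximum-likelihood variance `σ̂² = (1/n) Σ ŵ r²` with weights
normalized to mean 1; `p` counts the curve coefficients. AIC is the
standard `2p − 2 ln L̂` and `AICc = AIC + 2p(p+1)/(n−p−1)`; Akaike weights
are the softmax of `−Δ/2`. MSE is reported unweighted. On flat data the
rational family has the `b = a·c` ridge; this is detected via a
near-singular Jacobian and reported, not altered.

Group comparisons run two-tailed Mann-Whitney U tests per (age interval ×
ROI × direction), exact when the combined sample is ≤ 25 without ties and
asymptotic (tie-corrected) otherwise, with BH-FDR at 5% across the whole
family and the effect size `d = (median(S_m) − median(S_f))/(σ_m + σ_f)`
using sample standard deviations (ddof = 1). Default intervals: the
neonate baseline [0, 0.1], then (0.1, 6], (6, 12], (12, ∞) years.
Reference influence is the pairwise relative distance
`2|s_k − s_l|/(s_k + s_l)` and the relative standard deviation across
references (sample σ over mean).

Confidence bands are *pointwise* case-resampling bootstrap percentile
bands (not simultaneous bands — a deliberate, documented substitution),
labelled as such in every output; > 20% failed refits flags the band
unreliable.

## Synthetic data

The phantom is a left-right symmetric arrangement of soft-edged ellipsoids
(64³ grid, 2 mm spacing, world origin at the volume center) carrying a
mirror-symmetric multi-scale Gaussian-blob texture. The texture amplitude
(25–55% of the base intensity) is chosen so interior blocks have local
contrast comparable to tissue structure; without it the smooth boundary
dominates and block matching is blind to tangential (rotational) motion —
an aperture effect real T1 anatomy does not suffer from. Applying a
transform re-renders the geometry analytically (no resampling), so
registration-recovery experiments have alias-free ground truth. Additive
Gaussian intensity noise (σ = 0.5 on a 0–160 intensity scale) is seeded.

Synthetic cohorts mirror the study structure: 308 subjects by default, a
~12% neonate cluster (ages ≤ 0.1 y) serving as the normalization baseline,
the rest spread over (0, 6], (6, 12], (12, 19] in proportions
0.39/0.39/0.22, near-balanced sexes. True growth is rational per direction
with value 1 at birth and asymptotes 1.30–1.42, rendered relative to the
reference through constant per-direction factors < 1 (the atlas is larger
than a neonate). Noise on scaling factors is multiplicative lognormal
(σ = 0.03) since the factors are positive ratios; optional multiplicative
sex effects and per-reference lognormal jitter support the power and
reference-influence experiments. What the generator does *not* emulate:
MRI contrast changes with age, bias fields, segmentation errors and
non-linear anatomical variability — passing recovery tests demonstrates
correctness of the estimation machinery, not robustness to those factors.

## Problem sizes

The acceptance battery uses 100 noiseless and 50 noisy point-set instances
(20 points each, oracle = 20-start Nelder-Mead over the 9 parameters), 20
phantom registrations at 64³, 50 model-selection replicates at n = 300 /
σ = 0.02 with the cohort age distribution, 200 all-null replicates of the
4 × 21 × 3 test grid with the study's per-interval group sizes, 10⁴
quaternion pairs, and a 4-subject 32³ study run twice for bit-identical
determinism. Unit tests use a 48³ phantom where sub-percent accuracy is not
asserted.

## Known limitations

* Block matching captures moderate transforms (tens of degrees, tens of
  mm after centroid initialization); grossly misaligned or strongly
  symmetric inputs can settle in flipped poses, as with any local iconic
  method.
* Integer-offset search has no sub-voxel refinement; sub-voxel accuracy
  emerges only from aggregation over many blocks.
* The mid-sagittal estimator assumes approximate bilateral symmetry and
  degrades gracefully (grid mid-plane fallback) rather than failing.
* No reflections, 2D variants, non-linear registration, atlas
  construction, robust/trimmed fitting, or multi-modal similarity metrics.
* AICc model comparison assumes Gaussian residuals on the same data for
  all candidates; weights enter the likelihood as case weights.
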