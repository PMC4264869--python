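# Methods

This note documents the models and algorithms implemented in `gmia`, the
conventions and tolerances they use, what the synthetic-data generator does
and does not emulate, and the design decisions taken where more than one
defensible choice existed.

## Thin-plate splines

A 2-D thin-plate spline through source landmarks `s₁…s_k` is

    f(x) = a₀ + A x + Σᵢ wᵢ U(‖x − sᵢ‖),   U(r) = r² ln r,  U(0) = 0,

the unique interpolant minimizing the integral of squared second
derivatives ("bending energy").  Conventions fixed here:

* **Natural logarithm.**  `log₂` would scale all energies by a constant;
  one convention must be fixed so that reported energies are comparable and
  the independent dense-system oracle in the tests agrees exactly.
* **Bending energy is summed over the two output coordinates**:
  `BE = Σ_c w_cᵀ K w_c` with `K` the kernel matrix.  The sliding objective
  uses this summed form.
* **Side conditions** `Σ wᵢ = 0` and `Σ wᵢ sᵢ = 0` per output coordinate
  are satisfied by construction and asserted in tests (1e-8).
* **Kernel guard** `kernel_epsilon = 1e-12`: distances at or below it are
  treated as 0, the limit value of `r² ln r`.
* **Degeneracy.**  Duplicated or collinear source points raise a
  `DegenerateConfigurationError`; otherwise the bordered system matrix is
  checked against a condition-number cutoff of 1e12.  The system is
  assembled and solved in a *normalized source frame* (centroid-centered,
  RMS-scaled) — the TPS is equivariant under similarity transforms of its
  domain, so this changes nothing mathematically but makes the condition
  number (and hence the cutoff) scale-invariant; coefficients are converted
  back to raw coordinates in closed form.  An optional ridge term on the
  kernel diagonal (default 0) is available for nearly duplicated
  digitizations.
* The **bending-energy matrix** `B` (upper-left k×k block of the inverse
  bordered system, symmetrized) gives `BE(target) = Σ_c t_cᵀ B t_c` for any
  target; it annihilates the affine subspace, so affine deformations cost
  zero.  Agreement with `tps_fit`'s energy is held to 1e-8.
* `tps_inverse` inverts a fitted TPS pointwise by vectorized Newton
  iteration with the analytic Jacobian
  (`dU/dx = (2 ln r + 1)(x − s)`), starting at the query point.  It is
  intended for modest orientation-preserving deformations (rendering
  synthetic specimens, round-trip oracles), not folded maps.

## Sliding semilandmarks

Semilandmarks on open curves carry no anatomical along-curve homology;
their positions are estimated by minimizing the bending energy of the TPS
from a **fixed reference** (the sample Procrustes mean, computed once) to
each specimen.  Decisions:

* **Tangents** at a semilandmark are the unit vector connecting its two
  along-curve neighbors; at open-curve endpoints, the vector to the single
  neighbor.  Coincident neighbors raise an error naming the specimen and
  point.
* **Superimposition before sliding.**  Each configuration is first fitted
  to the reference by ordinary Procrustes (translation, scale, rotation).
  Bending energy is invariant to affine transforms of the target, so this
  does not change the objective, but it fixes the frame in which tangent
  parameters are solved; outputs are mapped back to the specimen's original
  digitizing frame, with anatomical landmark coordinates preserved
  bit-identically.
* **Joint exact solve.**  With `B` the reference's bending-energy matrix
  and one scalar slide parameter per semilandmark, the objective is a
  convex quadratic with Hessian `A[j,l] = (u_j·u_l) B[j,l]`; each iteration
  solves for the exact constrained minimizer of *all* semilandmarks of a
  specimen simultaneously, then recomputes tangents.  Energy is therefore
  non-increasing by construction (asserted every iteration in tests).
  Points stay on their tangent lines — the digitized curve is treated as
  locally linear and no re-projection step follows.
* **Convergence**: relative energy decrease below `tol = 1e-6` or
  `max_iter = 20` iterations, both exposed.
* The reference is computed **once** and held fixed (required for
  convergence to a non-degenerate mean when open curves lack anatomical
  end-point anchors).  The conventional alternating variant — refresh the
  reference as the Procrustes mean between passes — is available behind
  `update_reference=True`, default off.
* `slide_indices` optionally restricts sliding to a subset of
  semilandmarks, the rest acting as fixed anchors; this also provides a
  clean single-free-point configuration for the grid-search oracle tests.

## Generalized Procrustes Analysis

Partial Procrustes alignment: center, scale to unit centroid size, then
iterate optimal rotations against the evolving normalized mean until the
mean moves less than `tol = 1e-10` (Frobenius); hitting `max_iter` flags
`converged_ = False` rather than raising.  Rotations are proper
(reflections forbidden — specimens are imaged in standardized orientation).
The rotation gauge left free by GPA is pinned by rotating the final mean's
principal axes onto the coordinate axes, with the leading-axis sign chosen
so that the landmark with the largest absolute score projects positively —
this makes outputs bit-reproducible and similarity-invariant to 1e-8.

## Image registration

Backward warping: the TPS is fitted **from** the mean-shape template
landmarks **to** the specimen landmarks, each template pixel center is
mapped through it, and the specimen image is sampled there — exactly one
sample per output pixel, so areas of expansion leave no holes and areas of
compression produce no pile-ups.  Bilinear interpolation by default
(nearest/bicubic available); bilinear keeps intensities inside the convex
hull of their neighbors.

* **Coordinate convention**: arrays are row-major, origin top-left, pixel
  centers at integer coordinates; a landmark (x, y) addresses column x,
  row y.  tpsDig files are y-up and are flipped with
  `y' = (H − 1) − y` on load.  A one-pixel asymmetric fixture pins this in
  the tests.
* **Template frame**: the unit-size mean shape is scaled to the median
  specimen centroid size (preserving native pixel detail without inflating
  noise) and padded by a 5% margin; the resolution is configurable because
  no single choice is canonical.
* **Masks**: template pixels whose preimage leaves the source image are
  flagged invalid and excluded from every downstream statistic (statistics
  use the intersection of masks across the sample).  Preimages within 1e-6
  px outside the bounds are clipped in rather than masked — TPS evaluation
  carries ~1e-14 float noise that must not knock border pixels out.

## Texture statistics

RGB is scalarized to brightness — the unweighted per-pixel channel mean —
interpreted under a nuclear stain as inverse cell density (denser → darker).
Maps: pixelwise mean (optionally per RGB channel), sample variance with
denominator n−1 (unbiased; the paper-of-record convention is unstated, so
the choice is documented here), and signed group differences oriented
*later minus earlier* group, so developmental density increases appear
negative.  Variance maps use brightness; an RGB mode is retained as an
option.  Optional Gaussian pre-smoothing (mask-renormalized) is off by
default — raw pixel statistics are the primary object.

## Ordination

**Between-group PCA.**  Axes are the eigenvectors of the covariance of the
g group means (divisor g−1 — this affects eigenvalues only); individuals
are orthogonally projected.  Centering uses the *unweighted mean of group
means* by default so unequal group sizes are equitable (grand-mean
centering is an option).  At most g−1 axes exist, and in the full g−1
dimensions the projected group means reproduce their pairwise Euclidean
distances exactly (asserted to 1e-8).  Per-axis `variance_explained` is
the fraction of total individual variance; because axes are ordered by
group-mean variance, these fractions need not decrease.  Axis signs are
pinned by making the largest-magnitude loading positive.  The
decomposition runs through the SVD of the g×p mean matrix, so image-sized
p is cheap.

**Scaled two-block PLS.**  Dimension 1 is the leading singular pair of the
p×q cross-covariance between centered blocks, computed through the n×n
inner-product representation (economy SVD bases per block), so
pixel-scale blocks never materialize a p×q matrix.  The singular value
equals the covariance of the paired scores and is maximal over unit-norm
pairs.  The **scaling factor** is the slope of the first principal axis of
the 2-D score scatter (major-axis regression, both variables treated
symmetrically), signed so shape and texture scores associate positively;
joint scores average the shape score with the rescaled texture score.
Note major-axis slopes are scale-equivariant only up to the tilt of the
principal axis: multiplying one block by c multiplies the factor by c
exactly only in the perfectly correlated limit (tests assert 5%).
Subsequent dimensions deflate each block onto the orthogonal complement of
its earlier loadings, which makes within-block loadings exactly orthogonal.
A numerically zero cross-covariance yields a defined result with zero
singular value and a warning.

**Permutation tests.**  Statistic: Euclidean distance between group mean
vectors; relabelings preserve group sizes.  The add-one estimator
`p = (1 + #{permuted ≥ observed}) / (1 + n_perm)` avoids p = 0 and is
valid under exchangeability; `method="exact"` enumerates all distinct
splits (identity included, `p = #{≥ obs}/n_splits`).  Type-I calibration
at α = 0.05 over 500 null replicates is part of the acceptance suite.

## Synthetic data

The generator emulates a cross-sectional developmental study: three groups
of 7/8/5 specimens, each rendered as a fin-like object — a half-elliptical
outline and a straight midline band (sharp, landmark-digitized structures)
over a smooth intensity gradient, with 4 anatomical landmarks and three
open semilandmark curves (26 semilandmarks at defaults).

Per specimen: the template landmarks are displaced by the group's smooth
shape effect (an elongation/narrowing field, quadratic in the normalized
chord, scaled per group by α = 0, 1, 1.6) and an individual affine wobble
(entries N(0, 0.015) — shear/anisotropy survives Procrustes and provides
within-group shape variance).  The TPS through these "true" landmarks is
the specimen's forward deformation; images are rendered by evaluating the
planted field at the Newton-inverted deformation on a 4× supersampled grid
and box-downsampling, so sharp edges are consistently anti-aliased and the
registration round trip is exact up to interpolation error.  Texture
effects: a Gaussian blob (σ = 12 px) whose amplitude darkens with group
(0, −0.12, −0.22 — density increasing with age), two fixed "variance
regions" with per-specimen N(0, 0.1) amplitudes (spatially structured
individual variation), and iid pixel noise (sd 0.02).  Digitized landmarks
are the true ones with semilandmarks jittered *along* the local tangent
(uniform ±2.5 px, applied in the template frame and mapped forward, so the
unjittered position is a recoverable ground truth for sliding) plus
isotropic digitization noise (sd 0.4 px).  All noise magnitudes were
chosen once as plausible for stereomicroscope digitization at this image
scale (128×160 px) and are recorded in `SyntheticSpec`.

What the generator does **not** emulate: photorealistic tissue texture,
stain chemistry, emerging discrete structures (fin rays appearing between
stages), uneven illumination, or digitization errors correlated along
curves.  Passing tests therefore demonstrate correctness of the estimators
under known smooth deformations and additive intensity effects — not
robustness to every failure mode of real microscopy.

A null constructor (`null_spec`) removes all group effects; across 200
replicates the full landmark pipeline (generation → sliding → GPA →
permutation test) yields uniform p-values (Kolmogorov–Smirnov, α = 0.01),
confirming the pipeline manufactures no spurious group signal.

## Problem sizes and tolerances in the acceptance run

`scripts/acceptance.py` uses: 100 random configurations for TPS
exactness/affine invariance, 50 specimens across 5 seeds for sliding
monotonicity, 20 similarity-recovery replicates, 10 round-trip cases at
256×256, 25 bgPCA exactness replicates, 500 permutation null replicates at
n_perm = 199, and the full default synthetic design (20 specimens,
128×160 px) for the end-to-end quantities.  These sizes keep the whole run
in the minutes range on a single CPU while leaving each property's
tolerance (1e-8…1e-10 for algebraic identities, 2× the bilinear baseline
for the warp round trip, 5 px for blob localization) comfortably testable.

## Known limitations

* 2-D only; no closed-curve or surface semilandmarks; no
  minimum-Procrustes-distance sliding criterion (bending energy only).
* TPS inversion (used in rendering only) assumes an orientation-preserving
  deformation; strongly folded maps are out of scope.
* No cross-validated bias correction for bgPCA at small n; no intensity
  normalization across specimens beyond [0, 1] scaling — standardized
  imaging is assumed.
* `variance_explained` of texture bgPCA depends on the registered-image
  resolution through the pixel count; comparisons should fix the template
  scale.
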