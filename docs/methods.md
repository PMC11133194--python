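# Methods

## Model

The package couples a two-way predictor block X (I objects × L covariates)
with a three-way criterion block Y (I objects × J attributes × K sources)
through a shared object mode.  X is decomposed through components that are
linear combinations of the covariates, A = X W_X, with loadings P_X; the
object-mode matricization Y_A (I × JK) is regressed on the same components,
and the JK × R1 regression coefficient matrix is constrained to a Tucker3
structure, P_Y' = G_A (C ⊗ B)', with orthonormal attribute components B
(J × R2), orthonormal source components C (K × R3) and a core array G
(R1 × R2 × R3).  Constraining B and C to orthonormal columns loses no
generality for the Tucker3 structure (any non-singular transform can be
absorbed into the core); the scores A are unconstrained beyond lying in the
column space of X.

The estimation criterion is the α-weighted sum of the two normalized
residual sums of squares.  Internally the updates work on the equivalent
unnormalized concatenated form ‖Q − A S'‖² with
Q = [√β X | √(1−β) Y_A] and β = α‖Y_A‖² / (α‖Y_A‖² + (1−α)‖X‖²); the two
forms differ by the fixed constant
(α‖Y_A‖² + (1−α)‖X‖²)/(‖X‖²‖Y_A‖²), which is asserted to 1e-12 in the
tests.  Reported losses are always on the normalized scale, and the block
norms entering the criterion and β are those of the preprocessed matrices
that actually enter the fit.

## Matricization convention

Mode-A unfolding sends entry (i, j, k) to column k·J + j (0-based; attribute
index fastest), so the columns of Y_A align with the rows of the Kronecker
product C ⊗ B; the core is matricized the same way (G_A column r3·R2 + r2).
Mode-B unfolding uses column k·I + i and mode-C column j·I + i.  This is the
single most fragile convention in the code base and is pinned by dedicated
index-arithmetic and round-trip tests.

## Pre-processing

Predictors are autoscaled per column (mean 0, sd 1, n−1 denominator).  The
criterion array is centered across objects within each (attribute, source)
cell and scaled to unit pooled variance per attribute: one scale per
attribute across all sources, i.e. Σ_{i,k} y²_{ijk}/(I·K−1) = 1.  The pooled
(rather than per-cell) scale keeps profiles of one response comparable
across sources; a per-(attribute, source) autoscaling variant is available
(`y_scale="attribute-source"`) but is not the default.  The n−1 denominator
is a convention; any overall rescaling of a block is absorbed by the loss
normalization, so fitted subspaces are unaffected.  The fitted statistics
are stored so new observations can be transformed identically (required by
interpolation) and inverted.

## Estimation

Each ALS cycle performs four exact conditional minimizations:

1. **W-step.**  A is re-estimated through its defining parameterization
   A = X W.  Minimizing ‖Q − X W S'‖² gives W = (X'X)⁺ X' Q S (S'S)⁺.
   Parameterizing through W rather than a free A keeps the scores in the
   column space of X at every iteration, which is what makes the
   interpolation identity a = x'W exact for training rows and the
   regression-weight factorization Y_A ≈ X (W_X P_Y') hold.  A free-A
   variant would satisfy A = X W_X only at convergence, if at all.
2. **B-step.**  With G fixed and B'B = I, the Y-residual is minimized by the
   orthonormal Procrustes solution: B = U V' from the SVD of
   Y_B (C ⊗ A) G_B'.
3. **C-step.**  Analogous, from Y_C (B ⊗ A) G_C'.
4. **Regression step.**  P_X' = (A'A)⁺ A'X and G_A = (A'A)⁺ A'Y_A (C ⊗ B)
   (using B'B = C'C = I).

Each step can only decrease the criterion, so the loss history is
non-increasing; this is asserted per iteration in the tests.  X'X is
routinely rank-deficient when L ≥ I, in which case the minimum-norm
(pseudoinverse) solution is used silently; a singular A'A in the regression
step triggers a warning because it signals collapsed components.

**Initialization.**  Rational: B0 and C0 are the leading eigenvectors of
Y_B Y_B' and Y_C Y_C'; A0 comes from the Gram matrix of the unweighted
concatenation [X | Y_A].  Eigenvector signs are fixed (largest-absolute
entry positive) so the rational start is deterministic.  If a Gram matrix
has rank below the requested count, the basis is padded with an orthonormal
complement and a warning is emitted.  Random starts draw standard-normal
entries (B0, C0 then orthonormalized by QR); perturbed starts add
N(0, scale²) noise to the rational start and re-orthonormalize.  Before the
first recorded loss, every start is completed into a feasible state: G and
P_X by regression, then one W-step so A lies in the column space of X —
otherwise the first W-step could (legitimately) increase the loss relative
to an infeasible A0.

**Multi-start and convergence.**  Default 20 starts: 1 rational + 19
perturbed at scale 0.1 (configurable to random starts).  One master seed
spawns independent per-start streams.  Convergence when the loss decrease
drops below tol (default 1e-8) relative to the previous loss, or at 500
iterations; the lowest-loss start wins.  After fitting, per-column
reflections make the largest-absolute entry of each B, C and A column
positive, with the core (and P_X, W_X for A) absorbing the flips — output is
then reproducible up to the model's genuine rotational indeterminacy.

**Limiting cases** (used as oracle tests): α = 1 makes the score space equal
the top-R1 principal-component subspace of X; α = 0 with R2 = J, R3 = K
makes the fitted criterion equal rank-R1 reduced rank regression of Y_A on
X.  Both are verified against independent implementations (scikit-learn PCA;
an SVD-of-projected-Y oracle), and on tiny rank-(1,1,1) problems the ALS
loss is checked against a 50-start BFGS minimizer of the raw criterion.

## Model selection

All valid complexities between (1,1,1) and a maximum are fitted (validity:
each rank at most the product of the other two, and within the data
dimensions, with R1 ≤ min(I, L + J·K)).  Per complexity c = R1+R2+R3 the
lowest-loss model is kept (ties broken lexicographically on the rank
triple); the lower-left convex hull of (c, loss) is retained, keeping
collinear interior points; interior hull points receive the st-ratio of
successive slope changes, and the largest st wins with ties (within a 1e-9
relative band, to absorb floating-point noise in exactly-linear scans) going
to the lower complexity.  Hull endpoints are never selected.  With fewer
than three hull points the st-ratio is undefined and the lowest-loss model
is returned with a warning.  The fit measure is the converged multi-start
loss on the normalized scale.

## Rotation

B, C and P_X can each be varimax-rotated (or given an explicit orthogonal
matrix).  The core is counterrotated by the transposed rotation along the
matching mode; rotating P_X applies the same rotation to A and W_X so the
shared first-mode factorization of both blocks stays consistent.  All fitted
values and the loss are exactly invariant, which the tests assert to 1e-10
for varimax and for arbitrary random orthogonal rotations.  Varimax uses the
classical pairwise-sweep algorithm with the closed-form quartic angle and
Kaiser row normalization (applied during the search, undone after — row
scaling commutes with the column rotation).  The pairwise form is exact for
each column pair and does not stall on symmetric loading configurations, a
failure mode of the SVD-based fixed-point iteration.  Core-simplicity and
joint component/core rotation criteria are out of scope.

## Biplots

Every construction is an exact factorization whose full-dimensional marker
inner products reproduce a model matrix; plots truncate to the first two
marker columns (for joint biplots, the two largest singular values of the
core slice).  The full-dimensional coordinates are always retained in the
returned object so the identities can be tested.

- **Joint biplot** (reference component r): SVD of the core slice G_r
  splits M1 G_r M2' into markers (n1/n2)^{1/4} M1 U Δ^{1/2} and
  (n2/n1)^{1/4} M2 V Δ^{1/2}; the fourth-root level-count factors balance
  marker spread between modes and cancel in the product.
- **Interactive biplot**: rows of A against the JK rows of P_Y, labels
  `S<k>RP<j>`; reproduces the fitted Y_A.  Filtering to one attribute
  (markers across sources) or one source is supported.
- **Triplot**: the interactive biplot plus the L rows of P_X; A P_X'
  reproduces the fitted X.
- **Regression-weight biplot**: rows of W_X against rows of P_Y; inner
  products give Z = W_X P_Y', and X Z equals the fitted Y_A.
- **Interpolation**: a new raw profile x is transformed with the stored
  preprocessing and placed at a = x'W_X; training rows land exactly on their
  own score rows, the raw covariate means land at the origin, and response
  predictions follow as a P_Y'.
- **Graded scales**: ticks at μ·w along a marker direction, labeled with the
  original-units value mean + sd·μ, so μ = 0 labels the variable mean at
  the origin.

When R1 > 2 the displayed plane is the first two score columns; other
conventions (e.g. reordering components by explained variation) can be
applied upstream via an explicit rotation.

## Synthetic data generator

The generator emulates the model: random scores A, random loadings P_X,
orthonormal B and C, random core G; X_signal = A P_X' with
W_X = X_signal⁺ A so A = X W_X holds exactly in the noiseless limit, and
Y_signal from the Tucker3 expansion.  i.i.d. Gaussian noise is added per
block with the standard deviation set from the requested Frobenius
signal-to-noise ratio (the realized ratio therefore fluctuates around the
request, within a few percent at ≥1000 cells), matching the least-squares
error model of the criterion.  Defaults are 8 objects × 7 attributes × 6
sources with 10 covariates at complexity (2, 2, 2) and SNR 10 — a small
persons × reactions × situations design with dispositions as predictors.

What the generator does *not* emulate: ordinal rating scales (data are
continuous Gaussian), heteroscedastic or correlated noise, outliers, and
misspecified structure (the true coefficient array is exactly Tucker3).
Passing recovery tests therefore demonstrates the estimator's correctness
under its own model, not robustness to the discreteness and
misspecification of real questionnaire data.

Note on recovery comparisons: preprocessing rescales each attribute, which
maps the true attribute components to diag(1/s) B (centering leaves B and C
untouched).  Recovery is measured as mean principal-angle cosine
(congruence) between the estimated subspace and this transformed truth.

## Problem sizes and numerics

Tests and the acceptance script use small designs (I ≤ 12, J, K, L ≤ 10)
with 2–5 ALS starts, which this model class resolves well and which keep
the whole suite at well under a minute plus ~20 s for the generic-optimizer
comparison.  Key tolerances: algebraic identities (biplots, rotation
invariance, loss-form proportionality) at 1e-10 to 1e-12; limiting-case
agreements at 1e-8 with ALS run at tol 1e-14–1e-15 since the comparison is
against closed-form oracles; ALS-versus-BFGS gap at 1e-6.  Degenerate
inputs: K = 1 collapses the source mode (C is 1 × 1); constant predictor
columns and attributes with no post-centering variation are hard errors
naming the offending variable; a zero-norm block makes the criterion
undefined and is rejected.

## Serialization

Datasets travel as labeled CSV (long or stacked criterion layout); fits as
a directory of full-precision CSV matrices plus meta.json, with the core
serialized long (r1, r2, r3, value) so no matricization convention is baked
into the files.  Readers parse floats in round-trip mode, so write→read is
lossless and the pipeline is bit-reproducible under a fixed seed.
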