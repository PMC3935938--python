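# Methods

This note documents the models implemented in `caudalmorph`, the choices
made where the design was genuinely open, and what the synthetic study can
and cannot demonstrate.

## Outline shape: elliptic Fourier analysis

A closed pygostyle silhouette is treated as a pair of periodic coordinate
functions x(t), y(t) over one traversal of the contour. Decomposition uses
the Kuhl–Giardina formulation: the polygon is parameterized by cumulative
chord length t_p (total T), and harmonic n contributes four coefficients

    a_n = T/(2π²n²) Σ_p (Δx_p/Δt_p) [cos(2πn t_p/T) − cos(2πn t_{p−1}/T)]

(b_n with sines; c_n, d_n analogously for y), plus the bias terms A0, C0.
Chord length approximates arc length; `efa_decompose(..., param="uniform")`
instead declares the vertices equally spaced in the curve parameter, which
makes decomposition the (near-)exact inverse of `efa_reconstruct`. The
distinction matters for round-trip testing: re-decomposing a reconstructed
curve under chord parameterization implicitly reparameterizes it by arc
length, so decompose∘reconstruct is only approximately idempotent
(≈1e−3 on normalized descriptors for realistic shapes) under the default,
and exact to polygonal-sampling error (~(πn/k)²/3) under `uniform`.

**Normalization.** Size, position, rotation and starting point are removed
by standardizing on the first-harmonic ellipse: phase
θ = ½·atan2(2(a₁b₁+c₁d₁), a₁²+c₁²−b₁²−d₁²), spatial rotation
ψ = atan2(c₁*, a₁*), division by the semi-major length. The result satisfies
a₁ = 1, b₁ = c₁ = 0 exactly, leaving 4N−3 free variables. The π-ambiguity of
the normalized frame is resolved deterministically: a₁ > 0 always, and the
remaining two-fold choice by the sign of the third moment of x of the
normalized outline (the positive x-axis points toward the longer extent),
falling back to a lexicographic coefficient comparison for symmetric
shapes. Invariance of the descriptors under similarity transforms and
start-point shifts is verified to 1e−6.

**Harmonic count.** Power per harmonic is P_n = (a_n²+b_n²+c_n²+d_n²)/2;
the retained count is the smallest N whose cumulative share of total power
reaches 99%. For a sample of specimens the mean cumulative-power curve
across specimens decides a single shared N. Decomposition order before
selection is N_max = 32. Note: with N retained harmonics the free variable
count is 4N−3 (e.g. N = 8 → 29, N = 10 → 37); published EFA datasets do
not always report the pair consistently, so the package derives the
variable count from N rather than taking either number on faith.

**Specimen handling.** Raster masks are traced with 8-connected
Moore-neighbour boundary following on the largest foreground component
(holes ignored; pygostyle silhouettes are simply connected), flipped to a
y-up frame so dorsal deflection has a consistent sign, and canonicalized
counterclockwise. Right-facing specimens can be mirrored with a flag before
decomposition; there is no automatic reflection alignment. Species means
are taken coefficient-wise on normalized descriptors.

## Linear morphometrics

Eleven vertebral metrics at three serial positions are averaged within
specimen (the duplicated middle-vertebra rows first), then within species.
Body size is the geometric mean of five skeletal measurements, computed on
species means. Size correction is a per-trait GLS regression on
intercept + size under the Brownian covariance (λ = 1), keeping residuals;
species-level regression is the only order compatible with a species-level
covariance matrix. Measurements are used on the raw scale by default
(`log10` available as a flag).

## Phylogenetic covariance and Pagel's λ

For a rooted tree with branch lengths, C[i,j] is the root-to-MRCA depth of
tips i, j (Brownian covariance). Pagel's λ multiplies the off-diagonal of C
by λ ∈ [0,1]: λ = 0 is a star phylogeny (no signal), λ = 1 Brownian motion.
The multivariate estimate maximizes the summed per-column ML GLS
log-likelihood (intercept-only mean, per-column variance) under a single
shared λ — the simplest model consistent with reporting one λ per dataset —
using bounded scalar optimization with endpoint checks, verified against a
101-point grid. Likelihoods are full ML (not REML) with all constants, so
values are comparable across λ. Covariance matrices with condition number
above 1e12 are refused outright; no silent ridging.

## Permutation signal test

The observed statistic is the minimum total squared change over ancestral
states with branch-length weights (weighted squared-change parsimony),
computed exactly as a Schur complement of the branch-weighted graph
Laplacian: L_obs = Σ_cols x'Sx with S = L_TT − L_TI L_II⁻¹ L_IT. Zero
branches get a floor of 1e−8 times the mean branch length. The null
shuffles species rows among tips; p = (#{L_perm ≤ L_obs}+1)/(n_perm+1)
(never exactly zero). The reported 0–1 index is 1 − L_obs/mean(L_perm),
clipped — a repository convention, since published consistency indices do
not state a formula; the p-value is the primary statistic. On a star tree
the statistic is permutation-invariant, so the test is exact but powerless
there by construction; with i.i.d. data on resolved trees the null is
exchangeable and the test holds its nominal level (verified at n = 500).

## Phylogenetic PCA and MANOVA

Phylogenetic PCA eigendecomposes the evolutionary covariance
R = (X − 1a)'C⁻¹(X − 1a)/(n−1) with a the GLS mean; scores are the centred
data on the eigenvectors, and components explaining ≥ 5% of total variance
are retained.

The MANOVA statistic is the Pillai–Bartlett trace V = tr(H(H+E)⁻¹) of the
ordinary between/within cross-products (chosen over Wilks for robustness to
non-normality). The ahistorical p uses the standard approximate-F
transformation (verified against statsmodels to 1e−10). The phylogenetic p
simulates n_sim datasets of multivariate Brownian motion on the tree with
rate matrix equal to the pooled within-group GLS covariance
(residual cross-products of the group-indicator GLS fit over n − G), keeps
labels fixed, and counts simulated traces ≥ observed with a +1 correction;
ties count as exceedances (conservative). Null calibration at α = 0.05 sits
in 3–8% over 500 runs, and with λ = 0 applied to C the simulation null
matches the F-based p in distribution.

## Phylogenetic flexible discriminant analysis

Both the trait matrix and the one-hot class indicator are whitened by the
inverse Cholesky factor of C(λ); the discriminant is fitted by optimal
scoring (regress whitened indicators on whitened [1, X]; generalized
eigenproblem of the fitted cross-products with the trivial constant score
deflated; scores normalized θ'(Y*'Y*/n)θ = 1). Classification, however,
scores each species on its **own** trait values: a whitened row is a
phylogenetic mixture of species, not any one specimen's morphology, and
classifying whitened rows against model centroids misclassified heavily
even on fully separable data. Distances use the optimal-scoring/LDA
correspondence weights 1/(α²(1−α²)) per axis, arithmetic class centroids,
and uniform priors (group sizes are unbalanced and no prior information
exists). At λ = 0 on a unit-depth tree the whole procedure is exactly
ordinary LDA (verified prediction-for-prediction against scikit-learn).

The discriminant λ maximizes the summed per-column GLS likelihood of the
traits given the class-indicator design. Misclassification is
resubstitution (training-set) error over all species, matching how rates
over a full study sample are conventionally reported; leave-one-out is a
deliberate non-default. Fits with p ≥ n − G predictors are refused with a
pointer to PCA reduction.

## Synthetic study generator

The generator emulates the study's design, not any specimen: 51 species on
a unit-depth Yule tree (pendant edges extended by one extra exponential
waiting time so no terminal branch is zero), five foraging classes, 2–4
specimens per species, and parametric pygostyle-like outlines.

The shape family is a superellipse (exponent 3.2) stretched by
*elongation*, tapered caudally (quadratic profile, *taper* 1 = pointed),
bent dorsally (*deflection*, quadratic midline), notched at mid-length
(Gaussian of depth *constriction* — the hourglass of aerial foragers), with
two fixed fine-scale features shared by all classes (a concave ventral
articulation facet at the cranial end and a convex dorsal lamina ridge),
both applied multiplicatively so boundaries cannot cross the midline.
Class parameter means encode the study's qualitative contrasts: divers
elongate and straight (wing-propelled longest and untapered, plunge divers
tapering gradually, foot-propelled pointed with moderate bend), aerial and
terrestrial foragers short and strongly deflected, aerial adding the
mid-constriction. Within-class parameter deviations evolve as Brownian
motion on the tree (marginal sd = the class sd at unit depth): heritable
variation is phylogenetically autocorrelated, and i.i.d. deviations would
put implausibly large shape jumps on near-zero branches, which a
GLS-weighted analysis then amplifies without bound. Specimen-level noise is
2% parameter jitter plus vertex noise of 0.5% of outline length — well
below between-class differences, as in the study's museum material.

Group labels are built from whole clades; the wing-propelled divers get
four independent origins (convergent, non-monophyletic — verified), other
classes one, the last class absorbing the remainder. Among 40 candidate
labelings the one whose closest cross-class tip pair is most
phylogenetically distant is kept: recently diverged sister species share
foraging ecology in real assemblages, and a class boundary across a
near-zero branch would again dominate GLS estimates.

What passing the end-to-end test shows: the pipeline recovers
shape-predicts-ecology (≤10% resubstitution error, near-chance after label
shuffling) when classes genuinely differ in outline shape under
phylogenetically structured noise, including for a convergent class no
clade-based rule can capture. What it does not show: performance on real
silhouettes (segmentation artifacts, asymmetric wear, imaging variation),
behaviour when class differences are subtler than the generator's, or
cross-validated (rather than resubstitution) accuracy.

## Numerical choices and degenerate inputs

- All stochastic operations take explicit seeds; a root seed fans out via
  `numpy.random.SeedSequence` (sub-seeds kept below 2³¹). Re-running any
  generator or analysis with the same seed is bit-identical.
- PSD factorizations try Cholesky first and fall back to a clipped
  eigendecomposition for rank-deficient rate matrices.
- Resampling by arc length iterates interpolation to its fixed point
  (≤12 rounds) so the operation is idempotent to 1e−9.
- Degenerate inputs raise: duplicate tip labels, missing branch lengths,
  empty images, components below `min_area`, non-closed chain codes,
  zero-perimeter outlines, degenerate first harmonics, constant size
  proxies, single-group MANOVAs.
- Problem sizes in the test-suite calibrations (e.g. 24-tip trees with 199
  null simulations, repeated 500×; 128-tip trees for λ recovery) were
  chosen to make Monte-Carlo error small relative to the tolerance being
  checked while keeping each check to seconds; the batched implementations
  (matrix-normal draws and Pillai traces vectorized over replicates) make
  larger runs cheap if needed.

## Known limitations

- The λ transform is the only tree transformation offered (no OU/kappa).
- The permutation-test index is a repository convention; comparisons with
  consistency indices from other software are not meaningful beyond rank
  order.
- pFDA posterior class probabilities are not exposed; only hard
  classifications and discriminant scores.
- The generator's vertebral measurement table carries size and position
  structure but no ecological signal; it exercises the measurement
  pipeline (aggregation, size correction, signal tests) rather than
  vertebral ecomorphology.
- Alternative backbone topologies are supported only by swapping the input
  tree; the package does not build or sample trees.
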