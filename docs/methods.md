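# Methods

## Model

The gray-level co-occurrence matrix (GLCM) of a quantized image counts,
for a set of displacement vectors δ, how often gray-level pairs (i, j)
occur as neighbors. `glcminv` treats the normalized GLCM in two ways:

- **original** — a probability mass function P over the N² pairs,
  P = X / ΣX; features are plain sums over P with integer indices
  i, j ∈ {1..N}.
- **invariant** — a discretized probability density P̃ on the unit
  square, P̃ = X / (ΣX · Δᵢⱼ) with cell area Δᵢⱼ = 1/N². Each feature is
  a Riemann sum approximating an integral of the underlying pair density:
  indices are rescaled to i/N, j/N ∈ (0, 1], joint sums carry Δᵢⱼ,
  marginal sums carry Δ = 1/N, and sums over the sum-marginal
  p̃ₓ₊ᵧ carry Δₓ₊ᵧ = 1/(2N−1) with index map 2(k−1)/(2N−1); the
  difference-marginal index map is (k+1)/N. As N → ∞ the sums converge,
  so the features become asymptotically invariant to the quantization.

Both formulations share one count matrix; the density is exactly N² times
the PMF. This yields exact closed-form relations used as test oracles:
Contrast/N², Dissimilarity/N, Autocorrelation/N², Sum-of-squares/N²,
N²·Energy, Entropy − 2 ln N, N²·Max-probability, Correlation unchanged,
and the invariant Homogeneity / Inverse difference coincide with the
index-normalized (Clausi) forms Σ p/(1+((i−j)/N)²) and Σ p/(1+|i−j|/N).

### Conventions and deliberate choices

- **Quantization** is affine with equal-width half-open bins on [a, b];
  the value b maps to level N. Out-of-range values are clipped by default
  (an opt-out raises instead). The output is surjective onto [1, N] for
  inputs spanning [a, b] and monotone in the pixel value.
- **Quantization limits.** Fixed global limits shared by the whole
  dataset are used in all experiments (per-ROI min/max limits are
  sensitive to single outlier pixels). For a single-texture analysis the
  limits come from that image's histogram (its min/max).
- **Offsets** are (row, column[, slice]) displacements on the stored
  array. Neighbor pairs whose displaced pixel falls outside the array or
  the ROI mask are skipped (both pixels must be inside the mask);
  nothing wraps. Multi-offset GLCMs are accumulated by summation.
  Semi-direction-invariant sets keep one of each ±δ pair and add the
  transpose afterwards, which is exactly equivalent to counting both
  directions and always yields a symmetric matrix.
- **Logarithms** are natural throughout, with 0·log 0 := 0. In HXY1/HXY2
  a zero marginal product contributes 0 when its weight is 0.
- **Shared mean μ** (Cluster prominence/shade, Sum of squares) is the
  common marginal mean for symmetric GLCMs; for asymmetric GLCMs
  (μₓ+μᵧ)/2 is used.
- **Cluster exponents:** prominence uses the cube and shade the 4th
  power here. Much of the wider literature swaps the two; the convention
  is fixed and documented rather than inferred per source.
- **Sum-marginal normalization.** With the printed differentials the
  invariant sum-marginal satisfies Σ p̃ₓ₊ᵧ(k)·Δₓ₊ᵧ = N/(2N−1) (≈ ½),
  not 1: the 2N−1 cells of the sum variable span a width-2 interval while
  Δₓ₊ᵧ = 1/(2N−1) is half the true cell width. The definitions are kept
  as printed — the factor is the same at every N, so invariance across
  quantizations is unaffected — and the tests assert the N/(2N−1) value.
- **Degenerate inputs.** Correlation raises on zero marginal variance;
  the information measure of correlation 1 raises when |max(HX, HY)| <
  1e−12 (for the invariant variant this happens exactly when a marginal
  density is uniform, since differential entropies cross zero). The
  maximal correlation coefficient — the second-largest eigenvalue (by
  real part) of Q(i,j) = Σₖ p(i,k)p(j,k)/(pₓ(i)pᵧ(k)) — is excluded from
  the default feature set as numerically unstable on sparse GLCMs; a
  flag returns √λ₂ for the older convention. Q terms with a zero
  marginal are dropped (those gray-levels are unvisited).
- **Dithering** (uniform noise on ±amplitude/2 added before
  quantization) is available for integer-valued inputs; the default
  amplitude 1.0 equals one native gray-level step. The continuous
  synthetic textures need no dithering.

## Synthetic data

`gaussian_glcm` discretizes a bivariate normal density at GLCM cell
centers ((i−½)/N, (j−½)/N) — defaults mean (0.5, 0.5) and covariance
diag(0.02, 0.02) place a centered, clearly resolved blob at any N ≥ 8 —
to exercise both normalizations without an image.

`gaussian_random_field` synthesizes stationary textures by smoothing
white Gaussian noise with an isotropic Gaussian kernel (periodic
boundaries), rescaled to exact unit stationary variance; the
`correlation_length` parameter is the kernel standard deviation in
pixels. `two_class_sample` draws labeled sets of such fields, optionally
plus white noise, with per-image seeds derived from the master seed by
counter, so everything is bit-reproducible.

These fields are a deliberately idealized texture model: stationary,
Gaussian marginals, second-order structure only. Real tissue images are
non-stationary, skewed and structured at several scales. Passing the
experiments below therefore demonstrates quantization invariance of the
feature pipeline, not realism of the texture model, and accuracies
obtained here do not forecast accuracies on clinical data.

## Experiments

Both classification scenarios use logistic regression with a weak fixed
ridge penalty (scikit-learn, C = 1.0) on features z-scored with
training-set statistics — without standardization the original-variant
features, which span orders of magnitude across quantizations, stall the
optimizer. Splits are stratified by class.

- **Scenario 1 (random-quantization training):** 100 models; each
  training image is assigned an independently random quantization from
  the sweep (drawn uniformly, per image and per model); all 19 default
  features are used. Accuracy is evaluated on the test set at every
  quantization; the grid stores mean and standard deviation over models.
- **Scenario 2 (fixed-quantization training):** one model per training
  quantization, with greedy forward feature selection maximizing mean
  validation accuracy averaged over all validation quantizations
  (strictly-positive-improvement stop rule; ties broken by canonical
  feature order; an empty selection falls back to the majority class).

**Problem sizes.** The packaged experiments run on 100 images/class at
64×64 pixels with the reduced sweep {8, 32, 128, 256} and global limits
[−4, 4]; the full 8–256-step-8 sweep (32 quantizations) is available
through `SweepConfig` for larger studies. The two classes are Gaussian
random fields with correlation lengths 1.5 vs 2.0 px. This separation is
chosen so the matched-quantization problem is essentially solved
(diagonal accuracy ≈ 1) while cross-quantization transfer is still
informative: with very well-separated classes (e.g. 1 vs 6 px) *both*
variants reach accuracy 1 for every train/test pair and the comparison
saturates. A chance-level control with identical generating parameters
for both classes verifies that accuracies stay within binomial noise of
the majority-class baseline.

**Invariance measurement.** One 256×256 field with correlation length 3
is quantized at N ∈ {16, 32, 64, 128, 256} with histogram-derived
limits. Every invariant feature except maximum probability changes by
less than 5% between N = 128 and N = 256, while the original energy
decreases and entropy increases monotonically in N. Maximum probability
is excluded because, as the density at the mode, it keeps growing with
resolution on noisy data. The relative-change criterion assumes the
feature is bounded away from zero; with histogram-derived limits this
holds for all 18 remaining features on these textures, but features with
zero crossings (cluster prominence, the entropy family) can make relative
drift ill-conditioned for other texture/limit combinations.

## Known limitations

- Invariance is asymptotic: below ~16 gray-levels the Riemann sums are
  crude, and at very large N (order of the pixel count) GLCMs become
  sparse and noise-dominated — in both regimes the invariant features
  inherit the original features' pathologies.
- The invariant entropy family and information measures change
  interpretation (differential entropy; possibly negative).
- Features are computed per image/ROI; sliding-window feature maps and
  other texture matrices (run-length, size-zone, gray-tone difference)
  are out of scope.
- Only affine quantization is implemented.
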