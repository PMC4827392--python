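# Methods

This note records the statistical model, the algorithmic choices and their
rationale, what the synthetic phantom does and does not emulate, and the
open design decisions. Everything here is implemented and tested in this
repository; problem sizes quoted are this package's own verification
choices.

## 1. Model

Let `X ∈ ℝ^{n×p}` and `Y ∈ ℝ^{n×q}` be column-centered subject-by-voxel
matrices of two co-registered modalities. PLS2 extracts `m` latent
components sequentially. Component `i` is the leading singular pair of the
current cross-covariance:

```
(wᵢ, cᵢ) = argmax  wᵀ Xᵢᵀ Yᵢ c      s.t. ‖w‖ = ‖c‖ = 1
tᵢ = Xᵢ wᵢ,   uᵢ = Yᵢ cᵢ,   bᵢ = tᵢᵀuᵢ / tᵢᵀtᵢ
```

followed by x-score deflation of **both** blocks:

```
pᵢ = Xᵢᵀtᵢ / tᵢᵀtᵢ,   qᵢ = Yᵢᵀtᵢ / tᵢᵀtᵢ
Xᵢ₊₁ = Xᵢ − tᵢpᵢᵀ,    Yᵢ₊₁ = Yᵢ − tᵢqᵢᵀ
```

Prediction for new data uses the factored operator

```
Ŷ = ȳ + (X_new − x̄) W (PᵀW)⁻¹ diag(b) Cᵀ
```

**Why this deflation.** X-score deflation of both blocks is the canonical
PLS2/NIPALS regression mode: it keeps the score vectors `tᵢ` mutually
orthogonal (verified in the tests) and makes the inner regression diagonal.
At the exact singular pair `c ∝ Yᵢᵀtᵢ`, so `diag(b) Cᵀ` coincides with the
textbook q-loading prediction `Qᵀ`; the test suite verifies the full
training prediction against an independently coded NIPALS to 1e-6 relative
error.

## 2. Subjects-space solver

For imaging data `p, q ≫ n`, so the `p×q` matrix `XᵀY` must never be
formed. With Gram matrices `Gₓ = XXᵀ` and `G_y = YYᵀ` (both `n×n`), the
x-scores of the leading pair are the leading eigenvector of `GₓG_y`. The
implementation solves the symmetric, numerically safer form
`Gₓ^{1/2} G_y Gₓ^{1/2}` (PSD square root via eigendecomposition with
clipped eigenvalues), back-projects `w ∝ Xᵀ(G_y t)`, `c ∝ Yᵀt`, and
deflates. The total cost per component is `O(n³ + n(p+q))` and peak memory
`O(n² + n(p+q) + m(p+q))`.

Signs are fixed deterministically (largest-|entry| weight coordinate made
positive) so fits are bit-reproducible.

The regression operator is kept factored (`W`, `(PᵀW)⁻¹`, `b`, `C`); its
condition is checked and a singular `PᵀW` (possible only with degenerate
inputs) raises rather than silently producing garbage. An allocation audit
(`tracemalloc`) asserts that fitting at `p = q = 10⁴` stays under 100 MB
peak — a single `10⁴×10⁴` float64 array alone would be 800 MB.

**PCR comparator.** Principal component regression on the same centered
blocks (leading X-eigenvectors, diagonal least-squares in score space) is
included because it is the natural straw man: its components chase X
variance regardless of Y. With a high-variance predictor-only distractor
component, one-component PCR regresses on the distractor and predicts
nothing, while one-component PLSR follows the cross-covariance. The
verification uses 200 training subjects so the weight's finite-sample leak
onto the distractor (≈ scale/√n) is well below the signal; at that size
PLSR's test error is lower in every probe seed.

## 3. Patch-based baseline

The local comparator predicts each target voxel by exhaustive
nearest-patch search: for voxel `v`, find the atlas subject (and optional
small spatial offset) whose predictor patch (side 5 by default, clamped at
image borders) is closest in SSD to the query's patch at `v`, and copy that
atlas's target value (patch center by default, patch mean optionally).

The implementation computes all SSDs exactly with box filters
(`uniform_filter` over squared difference volumes) plus a border-validity
correction, rather than looping over voxels; ties are broken
deterministically (lowest atlas index, then lexicographic offset), and a
nested-loop brute-force oracle in the tests confirms voxel-for-voxel
equality in 2-D and 3-D, for both aggregation modes and non-zero search
radii. A leave-one-out mode rebuilds the database without the queried
subject.

## 4. The phantom

`phantom.py` generates cohorts in which the modelled structure is planted
and therefore checkable:

- `m_true` latent components, each a Gaussian blob (σ = 1.5 voxels) per
  modality, unit-normalised; predictor and target supports are at
  **different** locations by default (the non-local regime). Setting
  `component_centers_y = component_centers_x` produces the purely local
  control.
- Per-subject loadings `s_kj ~ N(μ_group[j], 1)` shared across modalities —
  one latent score drives both maps, which is exactly the structure the
  cross-covariance decomposition assumes.
- A shared "ventricle-like" confound blob added to both modalities with
  per-subject amplitude `N(0.5, 0.125)` — joint variation that is real but
  disease-unrelated.
- Additive white Gaussian noise passed through the same smoothing kernel as
  the signal (FWHM 2 voxels, `σ = FWHM/2.3548`). This mirrors acquisitions
  resampled to a standardized resolution: the *whole image* lives at that
  resolution, so acquisition noise is spatially correlated with reduced
  per-voxel variance. `noise_sd` is the pre-filter standard deviation
  (default 0.2, i.e. loading-to-noise ratio 5). An earlier draft added
  white noise *after* smoothing; that variant is not a faithful model of a
  resolution-standardised image and drowns unit-norm spatial maps in
  `O(σ√N_voxels)` noise at any realistic σ.
- A region atlas over the target-modality supports (threshold at 50% of
  each map's maximum, overlaps resolved by nearest blob center), used for
  regional error summaries and for noiseless per-subject reference regional
  values — the phantom analogue of independently reported regional uptake
  summaries.

Default cohort: 16³ grid, 3 components, 80 subjects per group (HC, MCI,
AD). Group mean loadings — HC (0,0,0), MCI (1.0, 1.5, 0), AD (2.5, 0.2, 0) —
were chosen so the three components have well-separated population singular
values (gaps ≳ 3× the sampling error at 240 subjects) and near-zero
group-induced between-component loading correlation; component recovery is
then a property of the solver, not of a lucky draw.

**What the phantom does not emulate:** registration error, intensity
non-uniformity, partial-volume effects at tissue boundaries, non-Gaussian
group structure, site effects, or any spatial covariance beyond the single
resolution kernel. It is a verification instrument, not a simulator of real
acquisitions.

## 5. Analysis components

- **Discriminability.** Fisher LDA (pooled within-class covariance,
  ridge 1e-6) on latent scores, leave-one-out: each subject is scored by a
  discriminant fit without it (scores standardized per fold by training
  statistics). AUC is computed by the rank (Mann–Whitney) formulation and
  is verified to equal exhaustive concordant-pair counting. Components are
  ranked by |LDA weight| of the all-subject fit; the top 5 are reported.
- **Matching and reproducibility.** A component's identity across repeated
  fits is its concatenated (x-map, y-map) signature; concatenation is the
  stricter convention, since both spatial patterns must co-reproduce.
  Repeats are matched greedily strongest-first on |Pearson r| with
  threshold 0.5, verified against a sorted-pair-list oracle; reported is,
  per component of a reference repeat, the number of other repeats with a
  qualifying match that is also top-ranked there.
- **Evaluation.** Regional mean absolute error per held-out subject
  (mean over atlas regions of within-region mean |error|), Pearson
  correlation against reference regional values with a Fisher-z 95% CI,
  Cohen's d (pooled SD) for group contrasts of predicted regional means,
  and a paired two-sided t-test between the two synthesis methods'
  per-subject errors. Degenerate inputs (zero variance, too few subjects)
  raise or return defined sentinel outcomes rather than NaN.
- **Networks.** A weight map is binarised at a quantile of its |values|,
  opened morphologically (ball/disk structuring element) to remove
  speckle, and labelled with 6-connectivity (faces only); each cluster is
  reported with voxel count and dominant sign. Verified against a BFS
  flood-fill oracle.

## 6. Verification design and open decisions

One test per release property lives in `tests/test_acceptance.py`; all
oracles are independently coded naive implementations in
`tests/oracles.py`. scikit-learn appears only as an additional external
cross-check of the PLS fit, never in package code.

Two decisions deserve explicit discussion:

**The discriminability bound is inside its own sampling noise.** The
discriminability property plants a single component whose loadings separate
two groups at Cohen's d = 1.5 and asks for mean held-out leave-one-out LDA
AUC ≥ 0.85 over 10 repeats (100+100 test subjects each). But an *ideal
observer* reading the true planted loadings has
`AUC = Φ(d/√2) = 0.8556`, with per-repeat sampling standard deviation
≈ 0.026 at 100+100 subjects, i.e. ≈ 0.008 on the mean of 10 repeats. The
bound therefore sits ~0.7 SD below the ceiling: even a perfect decoder
clears it in only ~75% of seed draws. Measured decomposition at the
canonical seeds: ideal observer 0.846, best single fitted score 0.841,
full LDA 0.839 — the fitted pipeline loses only ~0.007 AUC to estimation;
the rest is estimator noise. The bound is asserted as agreed and fails
honestly at those seeds; the companion property (the separated component
top-ranked by |LDA weight|) passes 10/10. A robust bound at this design
would be ≥ 0.82, or d ≥ 1.8 for a 0.85 bound; neither change was made.

**Verification problem sizes are package choices.** Oracle equivalence runs
on 50 random datasets (≤12 subjects, ≤60 voxels, m ≤ 5, agreement
|cos| ≥ 1−1e-8); recovery and the latent-vs-patch comparison run on the
default 16³ phantom (240–300 subjects, 10 seeded repeats); the memory audit
runs at 10⁴ voxels. These sizes make the full suite run in about a minute
on one CPU while keeping every property in the regime it describes.

## 7. Limitations

- The solver extracts components sequentially; no cross-validated choice of
  `m` is built in (the experiment driver takes `m` as a design parameter).
- LDA assumes shared within-class covariance of scores; with very small
  held-out groups the LOO discriminant is noisy, and at least 2 subjects
  per class are required.
- The patch baseline is exhaustive within its search radius; it is meant as
  a rigorous comparator at phantom scale, not an approximate-nearest-
  neighbour engine for full-resolution volumes.
- Regional evaluation requires an atlas; on real data one must be supplied
  in the same space as the mask.
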