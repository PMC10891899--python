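# Methods

## Pipeline

The analysis is a five-stage chain over reflectance hypercubes
`data[row, col, band]` with paired binary vein masks (1 = vein, 0 = skin):

1. **I/O and cropping.** Cubes are read from ENVI BIL binary plus a
   plain-text header (supported dialect: BIL interleave, 32-bit float or
   16-bit unsigned, explicit byte order). Regions of interest are half-open
   `[row0, row0+height) × [col0, col0+width)` crops; no silent clamping.
2. **Image-level split.** `round(fraction · N)` images train, the rest
   test, permuted by a seeded generator. The split is by image, never by
   pixel, so test pixels come from scenes the classifier has not seen.
3. **Dimensionality reduction** (PCA, Folded PCA, or WaLuMI band
   selection), fitted on training pixels only and applied unchanged to test
   cubes. Fitting on all pixels would leak test statistics into the
   reducer; a config switch exposes the leaky variant for comparison but it
   is never the default.
4. **Linear SVM** on z-scored features, balanced class weights.
5. **Evaluation** by pooled (micro-averaged) confusion counts over all test
   pixels, plus optional morphological refinement of the predicted masks.

## Reducers

**PCA.** Covariance of the mean-centered pixel matrix,
`C = Xc' Xc / (n−1)`, eigen-decomposed with `numpy.linalg.eigh`;
eigenvalues sorted non-increasing. The full spectrum is retained on the
fitted estimator so trace conservation (Σλ = total band variance) is
checkable at any k.

**Folded PCA.** Parameters H (segments) and W (bands per segment). Each
mean-centered spectrum, zero-padded (H·W > F) or truncated with a logged
warning (H·W < F), is reshaped row-wise to H×W; the partial covariance
`Cp = Σ Aᵢ'Aᵢ / (nH−1)` is W×W. Three conventions are deliberate:

- *Normalisation 1/(nH−1)*: makes H=1 reproduce the PCA covariance exactly,
  which is the method's stated degenerate limit and is enforced by tests at
  1e−9 (eigenvalues) / 1e−8 (projections).
- *Per-band global mean-centering before folding*: required for the H=1
  limit to hold.
- *Eigenvector-major flattening with truncation to k*: the per-pixel
  projection AᵢV is H×W; features are ordered "all H values of component 1,
  then component 2, …" and cut at k. Under this reading "number of
  components" counts output features, which is the only interpretation that
  makes a feature count that is not a multiple of H (e.g. 310 with H=151)
  reachable.

**WaLuMI.** Mutual information between bands is estimated with the plug-in
joint-histogram estimator: each band uniformly quantized to `bins` levels
(default 64) over its own [min, max], MI in bits. The estimator is biased
upward by roughly (bins−1)²/(2n ln 2) for independent bands, which is why
the independence check in the tests uses n = 10⁴ at 8 bins against a 0.05
bit threshold. MI becomes the bounded dissimilarity
`D = 1 − MI/√(HᵢHⱼ)` (geometric-mean entropy normalisation; constant bands
have zero entropy and are maximally distant, D=1). Ward's linkage is applied
directly to D through the Lance–Williams recurrence

    d(ij,k)² = [(nᵢ+nₖ)d(i,k)² + (nⱼ+nₖ)d(j,k)² − nₖ d(i,j)²] / (nᵢ+nⱼ+nₖ)

without re-embedding in Euclidean space; merge ties break to the smallest
index pair, so the tree is deterministic. The dendrogram is cut at k
clusters and each cluster is represented by the band with the largest total
MI to its co-members (ties to the lowest index). MI as defined here is
purely band-pairwise — no spatial term enters the selection.

Eigenvector signs everywhere are fixed so the largest-magnitude entry is
positive; all reducer fits are deterministic functions of their inputs.

## Classifier

`LinearSVC` (squared hinge, L2) behind a thin estimator that stores only
the standardization vectors and the decision hyperplane, so fitted models
serialize to plain JSON. Defaults: C = 1.0, `class_weight="balanced"`,
tol = 1e−4, fixed iteration cap and seed. Balanced weighting matters:
vein pixels are typically 10–30% of a hand scene and an unweighted hinge
loss drifts toward the all-skin solution. Features are z-scored with
training-stack statistics (a linear SVM is not scale-invariant and
reduced features have wildly different variances by construction).

## Metrics and sweep

Counts are pooled over all test pixels before rates are formed
(micro-averaging); per-image averaging is available but not the default.
Rates are percentages; by construction recall + FNR = 100 and
FPR + specificity = 100 with shared denominators. Undefined ratios (e.g.
precision of an empty prediction) surface as NaN with a `RuntimeWarning`,
never as silent zeros. The band sweep refits reducer and SVM per k and
reports the smallest k attaining the maximal accuracy; the conventional
grid for a 462-band cube is 10, 20, …, 460, 462.

## Synthetic scene generator

The generator emulates what the analysis assumes about hand scenes, not
skin optics:

- **Spectra**: linear baseline + Gaussian bumps, clipped to [0, 1]. The
  default vein profile lies strictly below the skin profile across the
  visible range and adds a deoxygenated-haemoglobin-like dip near 760 nm;
  only this ordering is calibrated, not absolute reflectance values.
- **Geometry**: cubic-spline-smoothed random walks spanning the image,
  dilated by a disk of radius ⌊width/2⌋ — spatially coherent, vessel-like,
  guaranteed to occupy a fraction strictly between 0 and 0.5 of the frame.
- **Illumination**: a random quadratic surface rescaled to
  [1−s, 1+s], multiplying the spectrum per pixel (mimics uneven line-light
  illumination; default s = 0.1).
- **Noise**: i.i.d. Gaussian per (pixel, band), default σ = 0.01
  reflectance units, clipped to [0, 1] after addition.

Everything is a pure function of `SyntheticConfig` including its seed; the
geometry and render streams are decoupled sub-seeds so the same mask can be
re-rendered under different nuisance conditions.

What the generator does **not** model: push-broom line artifacts, specular
highlights, spatial texture within each class, depth-dependent vein
contrast, detector non-linearity. Passing tests on synthetic scenes
therefore demonstrate that the pipeline machinery is correct and that the
methods recover a recoverable signal — not that the accuracy figures
transfer to acquired hand imagery, where class overlap is far larger. At
the default noise the synthetic classes are Bayes-separable, which is why
desk-scale runs report accuracies near 100%.

## Morphology

Structuring elements: `disk(r)` = lattice points with dx²+dy² ≤ r²
(disk(4) has exactly 49 pixels), `line(L, θ)` = L collinear pixels through
the anchor (θ = 0° and 180° both horizontal), `square(s)` = s×s block
anchored at offset ⌈s/2⌉−1. Presets: PCA → erode disk(4), dilate
line(5, 180°); FPCA → erode disk(4), dilate square(2); WaLuMI → erode
disk(4), erode disk(2), dilate disk(2); one iteration per step, all
configurable. Outside-image pixels count as 0 for both operations, so
erosion is anti-extensive and dilation extensive away from the border;
interior duality (erosion = complemented dilation of the complement with
the reflected element) is exact and tested.

These presets target full-resolution imagery where vessels are tens of
pixels wide. On 64×64 desk-scale scenes with ~5-px vessels the disk(4)
erosion removes most vein structure, so refined accuracy collapses toward
the skin fraction — the acceptance output reports this honestly rather than
rescaling the elements.

## Problem sizes

Tests and the acceptance script run the study at 64×64×64 (six scenes,
4/2 split, ≈ 2.6 × 10⁵ training pixels), with the 462-band geometry
exercised where it is cheap (header parsing, fold index arithmetic, the
sweep grid). Full-scale defaults (PCA k=150; FPCA k=310 with a 151×3 fold;
WaLuMI 40 bands; 1024×1024 ROI crops of 2800×1600 captures) are the config
defaults for real data.

## Known limitations

- Only the BIL interleave and two numeric types are supported on disk.
- The MI estimator is the plain plug-in; no bias correction or adaptive
  binning.
- Ward linkage is O(F³) in the band count — fine for F ≤ 462, not for
  imaging spectrometers with thousands of channels.
- The SVM is linear by design; no kernels or probability calibration.
- Morphological presets are fixed recipes, not learned post-processing.
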