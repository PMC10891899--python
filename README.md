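# hsvein

Hyperspectral hand-vein detection: dimensionality reduction, per-pixel
linear-SVM segmentation, and morphological mask refinement for reflectance
hypercubes of the back of the human hand (400–1000 nm, up to 462 bands).

Accurate vein localisation matters for venipuncture and vascular surgery,
and is hardest exactly where clinicians need it most — paediatric patients,
high subcutaneous fat, darker skin tones. A hyperspectral camera records a
full reflectance spectrum at every pixel, so a vein/skin decision can be
made spectrally instead of from a single NIR contrast image. The obstacle is
dimensionality: a 2800×1600×462 cube is several gigabytes, and a per-pixel
classifier on 462 correlated bands is slow and overfit-prone. This package
implements the standard answer — reduce the spectral dimension first, then
classify every pixel — as a reusable, tested pipeline with three
interchangeable reduction backends and a seed-deterministic synthetic scene
generator for validation.

## Methods

Pixels are rows of an *n* × *F* matrix **X** (one column per band).

**PCA** (`SpectralPCA`) — eigen-decomposition of the band covariance
C = Xᶜᵀ Xᶜ/(n−1) of the mean-centered matrix; the projection
Y = Xᶜ P keeps the top-*k* eigenvectors.

**Folded PCA** (`FoldedPCA`) — each centered spectrum is folded row-wise
into an *H* × *W* matrix Aᵢ (*H* segments of *W* bands; the vector is
zero-padded or truncated to *H·W*) and the *W* × *W* partial covariance
Cp = Σᵢ AᵢᵀAᵢ/(nH−1) is eigen-decomposed. The per-pixel projection AᵢV is
flattened eigenvector-major and truncated to *k* features, which mixes
distant spectral segments at a fraction of the full covariance cost. With
H = 1 the method reduces exactly to PCA.

**WaLuMI** (`WaLuMIBandSelector`) — Ward's-linkage band selection using
mutual information. Pairwise MI between quantized bands,
MI<sub>ij</sub> = I(X<sub>i</sub>; X<sub>j</sub>), becomes the dissimilarity
D<sub>ij</sub> = 1 − MI<sub>ij</sub>/√(H<sub>i</sub>H<sub>j</sub>); bands are
agglomerated under the Ward Lance–Williams recurrence, the dendrogram is cut
into *k* clusters, and the band with maximal total MI to its cluster
co-members represents each cluster. Unlike the projections, the selected
features remain physical wavelengths.

Classification is a soft-margin **linear SVM** on z-scored features with
balanced class weights (veins are a minority class). Performance is reported
as accuracy, precision, recall, FPR and FNR in percent, micro-averaged over
all test pixels, with a band-count sweep (`band_sweep`) to locate each
method's optimal *k*. Predicted masks can be cleaned with per-method
morphological recipes (disk/line/square structuring elements).

## Worked example

Six synthetic 64×64×64-band scenes (four train, two test), PCA with 10
components, linear SVM:

```python
import numpy as np
from hsvein import (SyntheticConfig, generate_dataset, SpectralPCA, reduce_cube,
                    assemble_training, train_svm, predict_mask, confusion,
                    metrics, ConfusionMatrix)

pairs = generate_dataset(SyntheticConfig(seed=0), 6)
train, test = pairs[:4], pairs[4:]

pixels = np.vstack([cube.data.reshape(-1, cube.bands) for cube, _ in train])
reducer = SpectralPCA(n_components=10).fit(pixels)

ts = assemble_training([reduce_cube(c, reducer) for c, _ in train],
                       [m for _, m in train])
clf = train_svm(ts, seed=0)

pooled = ConfusionMatrix(0, 0, 0, 0)
for cube, mask in test:
    pred = predict_mask(clf, reduce_cube(cube, reducer))
    pooled = pooled + confusion(pred, mask)

rep = metrics(pooled)
print(f"test pixels: {pooled.total}  veins: {pooled.tp + pooled.fn}")
print(f"accuracy  {rep.accuracy:6.2f} %")
print(f"precision {rep.precision:6.2f} %")
print(f"recall    {rep.recall:6.2f} %")
print(f"FPR       {rep.fpr:6.2f} %   FNR {rep.fnr:6.2f} %")
```

prints

```
test pixels: 8192  veins: 1741
accuracy  100.00 %
precision 100.00 %
recall    100.00 %
FPR         0.00 %   FNR   0.00 %
```

At the generator's default noise (σ = 0.01 reflectance units) the two
synthetic classes are linearly separable after averaging over 64 bands, so
the pipeline recovers the ground truth exactly; the accuracy is a property
of the synthetic conditions, not a claim about real hands. Raising the noise
makes the numbers informative — at σ = 0.2 the same code prints
`acc 97.99  prec 92.09  rec 99.02  fpr 2.29  fnr 0.98`.

The same analysis runs from the shell over ENVI BIL files on disk:

```sh
hsvein generate --config config.yaml      # synthetic HDR+BIL cubes + PNG masks
hsvein run      --config config.yaml      # split, reduce, train, predict, report
hsvein sweep    --config config.yaml      # accuracy vs number of components
```

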