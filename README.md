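# bovw3d

Interpretable 3D bag-of-visual-words (BoVW) classification for volumetric
fluorescence microscopy.

## The problem

Volumetric fluorescence datasets — single-nucleus chromatin stacks, dense
timelapse fields of view — often differ between experimental conditions in
ways an expert can see but cannot reduce to one hand-crafted measurement: the
signal is structural, spatially distributed, and genuinely three-dimensional.
`bovw3d` summarizes each volume as a histogram of learned local 3D patterns
("visual words"), classifies conditions with a linear model, and — because the
model is linear — maps the decision back into the volume as an attention map
that shows *where* the discriminative structure lives and lets you quantify
*what* it looks like (blob fragmentation, co-occurrence texture).

## Method

For each single-channel volume `V` (axis order `(z, y, x)`, optional cell
mask):

1. **Normalization** — clip to the in-mask 5th–95th intensity percentiles and
   rescale to `[0, 1]`.
2. **Keypoints** — 3D difference-of-Gaussians scale space over
   `σ ∈ {1.0, 1.6, 2.2, 3.0}` voxels and 3 octaves; strict 3×3×3 extrema with
   `|DoG| >` a contrast threshold (bright blobs are DoG minima); a 3×3
   Hessian eigenvalue-ratio test removes edge-like responses.
3. **Descriptors** — on a cubic patch of edge `≈ 5σ·2^octave` around each
   keypoint, gradients (finite differences) are expressed *relative to their
   26-neighbors*: orientation differences `(Δθ, Δφ)` weighted by magnitude
   ratios `m_q/(m_p+ε)` fill a 4×8 histogram, L2-normalized. Relative
   measurement makes the descriptor robust to rotations and invariant to
   intensity scaling. Patches must lie fully in the volume with ≥ 50% of
   voxels in-mask.
4. **Encoding** — a K = 200-word codebook is learned on all descriptors by
   mini-batch sparse dictionary learning; descriptors are soft-assigned
   (sparse coefficients over all atoms). Per image, `usage_k = Σ_patches
   |c_k|`; usage vectors are TF-IDF reweighted (`idf_k = ln((1+N)/(1+df_k))+1`)
   and L2-normalized, making the representation invariant to keypoint count.
5. **Classification & attention** — L2-regularized logistic regression on the
   normalized vectors `x`, scored by stratified 5-fold cross-validated
   AUC-ROC (binary) or a confusion matrix (multiclass). Each word's
   contribution `c_k = w_k x_k` is redistributed to patches in proportion to
   their absolute word usage; patch scores render back over their cubic
   supports into a volumetric attention map, conserving `Σ_k w_k x_k` exactly.
6. **Quantification** — one global threshold (90th percentile of positive
   attention) defines high-attention voxels; 26-connected components give
   blob counts/volumes; 32-level, distance-1, zeros-ignored gray-level
   co-occurrence matrices give 13 Haralick features per high-attention patch,
   averaged over the 13 unique 3D directions.

## Worked example

```python
from bovw3d import BoVW3D, FixtureSpec, PipelineConfig, make_dataset

records, manifest = make_dataset(FixtureSpec(n_per_class=20, seed=0))
model = BoVW3D.from_records(records, config=PipelineConfig(seed=0))
results = model.fit()
print(results.summary())
```

```
3D Bag-of-Visual-Words results
==================================
images: 40  classes: [np.str_('A'), np.str_('B')]
keypoints/image: mean 337.0 (min 84, max 714)
accepted patches/image: mean 280.2
codebook: 200 words x 32 dims
AUC-ROC (5-fold CV): 1.000
attention threshold (global): 0.2848
  A: mean 13.3 high-attention blobs, mean blob volume 124.2 vox
  B: mean 24.6 high-attention blobs, mean blob volume 154.3 vox
high-attention texture (per-condition means):
  A: contrast 25.814, IDM 0.291, entropy 6.052
  B: contrast 12.457, IDM 0.302, entropy 6.264
```

Class A is the punctate synthetic condition, class B the smooth/homogeneous
one (see `bovw3d.synthetic_fixtures`). The cross-validated AUC of 1.000 says
the word-usage vectors separate the conditions perfectly at this noise level;
the texture block shows the direction of the difference inside high-attention
regions — the smooth class has lower co-occurrence contrast and higher
inverse difference moment (homogeneity), i.e. the classifier attends to
regions whose texture is smoother in class B, matching how the data were
generated. `results.save("run_dir")` writes vectors, keypoints, blob and
texture tables as CSV, models as JSON and attention maps as 32-bit TIFF.

The same workflow runs from the shell:

```bash
bovw3d simulate data/ --n-per-class 20 --seed 0
bovw3d run-all data/manifest.csv run/ --seed 0
```

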