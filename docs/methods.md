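# Methods

This note documents the models and procedures implemented in `bovw3d`, the
parameters that matter, the numerical conventions, and what the synthetic
fixtures do and do not establish.

## Pipeline model

The package treats a labelled set of single-channel 3D volumes as a
document corpus: local 3D structure is detected, described, quantized against
a learned vocabulary, pooled per image, and classified linearly. The linear
classifier is not incidental — its decision value decomposes exactly over
words and hence over patches, which is what makes the volumetric attention
maps faithful rather than approximate saliency.

### Intensity normalization

Each volume is clipped to the 5th–95th percentile window and affinely mapped
to [0, 1]. Percentiles are computed over in-mask voxels when a mask exists
(single-cell crops), otherwise over the whole grid (field-of-view mode, where
each frame is normalized independently). A constant window (p5 = p95) yields
an all-zero volume with a warning instead of an error: a batch over hundreds
of crops should not abort because one degenerate cell slipped through
segmentation.

### Scale space and keypoints

A Gaussian scale space is built at σ ∈ {1.0, 1.6, 2.2, 3.0} voxels per
octave, with 3 octaves obtained by decimating the most-blurred level by two
(the classic SIFT cascade; the octave base is therefore pre-smoothed before
subsampling). Differences of successive blurs approximate the Laplacian of
Gaussian. Sign convention: DoG = more-blurred − less-blurred, so bright blobs
are DoG *minima* and dark blobs maxima.

Keypoints are *strict* extrema of a 3×3×3 neighborhood — ties are excluded
because plateaus in quantized data would otherwise fire everywhere — with
|DoG| above a contrast threshold (default 0.01 on the [0, 1] intensity
scale). Border voxels with incomplete 26-neighborhoods cannot be extrema.
Edge-like responses are removed by a 3D analogue of the SIFT edge test: the
3×3 Hessian of the DoG is estimated by central differences at the candidate,
and candidates with max|λ|/min|λ| above 10 are discarded; candidates whose
stencil does not fit (volume border) or whose smallest eigenvalue vanishes
are treated as unreliable and discarded too. Octave coordinates are mapped to
original resolution by multiplying by 2^octave.

Scale space is isotropic in voxel units — axial anisotropy is *not*
compensated by per-axis σ. The detector is intended to run unchanged on
anisotropic confocal stacks; the anisotropy then simply changes which
physical structures appear blob-like, which is part of the regime the
field-of-view mode emulates.

Sub-voxel refinement and canonical orientation assignment are deliberately
absent: localization to the voxel grid is sufficient for patch extraction,
and rotation robustness is supplied by the descriptor instead.

### Relative-orientation descriptor

Gradients are computed once per volume at original resolution (central
differences, one-sided at borders) and shared by all octaves. For a keypoint
of effective scale σ_eff = σ·2^octave, a cubic patch of edge
round-to-odd(5 σ_eff) is extracted; patches that poke outside the volume are
rejected rather than padded, and patches with less than `min_mask_frac`
(default 0.5 — a judgment call, exposed in config) of voxels in-mask are
rejected so descriptors reflect cellular rather than background structure.

Within a patch, each in-mask voxel p with gradient magnitude above ε = 1e-8
contributes, for each of its 26 in-patch neighbors q, the weight
m_q/(m_p + ε) to the histogram bin indexed by

* Δθ = |θ_p − θ_q| ∈ [0, π] (polar-angle difference; reflective, since the
  polar angle itself lives on [0, π]), 4 bins, and
* Δφ = wrap(φ_p − φ_q) ∈ [−π, π) (azimuth difference; periodic), 8 bins.

The 32-bin histogram is L2-normalized per patch (zero stays zero), so
codebook atoms capture pattern shape rather than patch energy, and the
descriptor is exactly invariant to positive intensity scaling.

Two design points deserve flagging. First, the magnitude ratio is used as the
*accumulation weight* of a single orientation histogram rather than as a
separate binned axis; this is the main descriptor-design judgment call, and
bin counts (4×8) were chosen to keep the descriptor compact relative to the
200-word codebook. Second, pairwise angle differences measured in a fixed
spherical frame are exactly rotation-invariant only for rotations about the
polar axis; for general rotations the invariance is statistical, arising from
aggregation over all voxel–neighbor pairs. On smooth, blob-like patches — the
regime the detector selects for — the measured cosine similarity is ≥ 0.99
across all 24 axis-aligned grid rotations and ≥ 0.95 under ≤ 15° resampled
rotations (both re-verified by the acceptance script). Descriptors of highly
anisotropic, non-blob-like structure should be expected to be less stable
under rotation.

### Codebook, soft assignment, TF-IDF

A K = 200 atom dictionary is learned once on descriptors pooled across the
full dataset (even when downstream analysis is size-stratified) with
mini-batch sparse dictionary learning, seeded for determinism; atoms are
unit-normalized. Descriptors are soft-assigned by sparse coding (lasso-LARS;
transform penalty 0.1 by default — the sparser the code, the more a patch
concentrates on few words and the sharper the attention redistribution).
Fewer descriptors than K is an error suggesting a smaller codebook.

Image-level usage is the sum of *absolute* coefficients per word. Sparse
codes can be negative, but term frequencies and the attention redistribution
presuppose non-negative usage; pooling |c| makes both well-defined. A
positive-part alternative is exposed behind a flag. The smoothed inverse
document frequency idf_k = ln((1+N)/(1+df_k)) + 1 (presence threshold 1e-8)
is fitted on the corpus and reused at inference; any monotone idf preserves
ranking behavior. Vectors are then L2-normalized, which makes the
representation exactly invariant to duplicating patches (and hence largely
insensitive to keypoint count / cell size). UMAP embedding of the normalized
vectors is presentation-layer only; nothing downstream consumes it.

### Classification, attention, conservation

Logistic regression with L2 penalty (C = 1 default, lbfgs, tol 1e-8 so
repeated fits agree). Binary performance is AUC-ROC from pooled held-out
probabilities under stratified 5-fold cross-validation with a fixed seed;
an in-sample flag exists because evaluation protocols vary between studies
and both are legitimate summaries of a fitted representation. Multiclass
performance is reported as a confusion matrix.

Attention: with x the normalized TF-IDF vector and w the weight vector (the
positive-class weights for binary; the true-class row by default for
multiclass, predicted-class optional), word k contributes c_k = w_k x_k.
Patch p receives Σ_k c_k |c_pk| / Σ_q |c_qk|, words with zero total usage
contributing nothing. The intercept is excluded — it has no spatial support —
so the conservation law is Σ_p score_p = Σ_k w_k x_k, which holds to machine
precision and is asserted in tests at 1e-6 relative tolerance. Rendering
spreads each patch's score uniformly over its cube (score/edge³ per voxel),
chosen over Gaussian weighting (available as an option) because uniform
spread conserves the decomposition exactly under addition of overlapping
patches. The per-image min–max rescaled copy is for visualization and
thresholding; an all-equal render rescales to zeros with a warning.

### High-attention blobs and texture

The global attention threshold defaults to the 90th percentile of positive
voxel scores pooled over the whole dataset's rescaled maps — a reproducible
rule standing in for an empirical choice — and is overridable by an absolute
value; thresholding and blob analysis run on the rescaled positive maps by
default (the signed maps can be used instead). Connected components use
26-connectivity by default (6 and 18 selectable), labelled in scan order.

For texture, in-mask intensities are clipped to the 1st–99th percentiles,
rescaled, and quantized to levels 1..32 with level 0 reserved for background.
High-attention patches reuse the keypoint patch geometry (those whose centers
fall in high-attention voxels), which keeps the provenance between attention
and texture exact. Per patch, co-occurrence matrices are accumulated at
distance 1 over the 13 unique 3D direction offsets, excluding any pair
involving level 0, symmetrized, and normalized to sum 1 per direction; the 13
Haralick statistics (ASM, contrast, correlation, sum-of-squares variance,
inverse difference moment, sum average/variance/entropy, entropy, difference
variance/entropy, and the two information measures of correlation) are
computed per direction with log base 2 and averaged over directions that had
at least one valid pair. Conventions worth noting: features are functions of
matrix *indices* (0-based), difference variance is the variance of the
|i−j| distribution, and correlation and the information measures are defined
as 0 on zero-variance (degenerate) matrices, with the patch flagged. A patch
with no valid pair anywhere is flagged invalid and excluded from pooling.
Per-image summaries are feature means over valid patches; per-condition
kernel density estimates (Gaussian, Scott's rule bandwidth) are
presentation-layer only.

### Size stratification

When a perturbation changes cell size, stratifying reduces size-driven
overlap: the stratifier keeps perturbed images above their condition median
volume and controls below theirs (medians per condition by default, global
optional; exact-median ties excluded). Volumes come from the 3D masks.

## Synthetic fixtures

The generator emulates the two study regimes at desk scale: (i) isotropic
single-nucleus crops — ellipsoidal masks (48³ grid, radius 16 ± 1.5 voxels,
mild ellipticity) whose interior is a sum of Gaussian blobs plus background
0.1 and Gaussian noise σ = 0.05, with a punctate class (30 blobs, σ = 1.6,
amplitude 1.0) against a smooth class (4 blobs, σ = 6.0, amplitude 0.6) that
is also volume-shifted ×1.5, emulating perturbation-driven nuclear
enlargement; and (ii) anisotropic whole-FOV stacks with many overlapping
cells, no masks, and axial decimation by 4, emulating coarse confocal
z-sampling, with four conditions crossing texture class with a pre/post
amplitude change. Sizes were chosen so a full two-class run (40 images)
completes in about a minute on one CPU while still producing several hundred
keypoints per image. All outputs are fully determined by the seed, and
ground truth (blob centers, scales, nucleus volumes) is recorded so
localization and trend-recovery are assertable.

What passing on fixtures shows: the machinery is correct (oracle-exact
extrema, conserved attention, invariances) and the representation recovers a
planted, texture-borne class difference in the right direction (smooth class
→ higher inverse difference moment, lower contrast in high-attention
regions). What it does not show: performance on real microscopy — the
fixtures have no PSF, no photobleaching, no inter-channel structure, simpler
noise than cameras produce, and a much larger effect size than a subtle
biological perturbation; AUC = 1.0 here is a property of the planted effect,
not a general performance claim.

## Numerical conventions and degenerate inputs

* Axis order (z, y, x); 0-based voxel coordinates throughout.
* ε = 1e-8 for gradient-magnitude floors, TF-IDF presence, and usage
  positivity; descriptor and vector norms of exactly zero are left as zeros.
* Constant inputs: normalization → zeros + warning; descriptor → zero vector;
  texture quantization → level 1 + warning; rescaled attention → zeros +
  warning. Pipelines continue past all of these.
* Determinism: every stochastic stage (dictionary learning, CV folds, UMAP,
  the generator) takes an explicit seed; identical seeds reproduce numeric
  outputs exactly.

## Known limitations

* Intensity-keypoint driven: volumes with nearly homogeneous signal produce
  few keypoints and an impoverished representation (an image with no accepted
  patches yields a zero vector and a warning).
* One channel at a time; joint multi-channel organization is out of scope.
* Rotation robustness is statistical, not exact, away from blob-like patches.
* Segmentation is an input, not a capability; mask quality bounds everything
  in the single-cell mode.
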