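"""Logistic regression on image vectors and attention-map decomposition.

An L2-regularized logistic regression is trained on the TF-IDF + L2-normalized
word-usage vectors (binary control-vs-perturbation, or multiclass). Because
the decision function is linear, the image-level score decomposes exactly:
the contribution of word k is c_k = w_k * x_k, and each word's contribution is
redistributed to the patches of the image in proportion to each patch's
absolute usage of that word. Summing over words gives one scalar attention
score per patch, and by construction the patch scores sum to the linear term
of the classifier score (the intercept carries no spatial support and is
excluded). Patch scores are rendered back into the volume over the patches'
cubic supports to give a volumetric attention map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .bovw_encoding import ImageVector, PatchEncoding
from .rihog3d import Patch


@dataclass
class ClassifierModel:
    weights: np.ndarray  # (K,) binary or (n_classes, K) multiclass
    intercept: np.ndarray
    classes: np.ndarray
    C: float = 1.0
    estimator: object = None

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def weight_vector(self, class_label=None) -> np.ndarray:
        """Weight vector for decomposition: binary uses the positive-class
        weights; multiclass uses the row of the requested class."""
        if self.weights.ndim == 1:
            return self.weights
        idx = int(np.nonzero(self.classes == class_label)[0][0])
        return self.weights[idx]


@dataclass
class AttentionMap:
    patch_scores: np.ndarray
    volume_render: Optional[np.ndarray] = None
    rescaled: Optional[np.ndarray] = None
    image_id: str = ""


def train_classifier(
    vectors: Sequence[ImageVector],
    labels: Sequence,
    C: float = 1.0,
    seed: int = 0,
    max_iter: int = 5000,
) -> ClassifierModel:
    """Fit L2-penalized (multinomial) logistic regression on normalized vectors.

    Deterministic given data: lbfgs with a tight tolerance so repeated fits
    agree to numerical precision.
    """
    X = np.vstack([v.normalized for v in vectors])
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    clf = LogisticRegression(
        C=C, solver="lbfgs", tol=1e-8, max_iter=max_iter, random_state=seed
    )
    clf.fit(X, y)
    w = clf.coef_[0] if len(clf.classes_) == 2 else clf.coef_
    return ClassifierModel(
        weights=w, intercept=clf.intercept_, classes=clf.classes_, C=C, estimator=clf
    )


def evaluate_auc(model: ClassifierModel, vectors: Sequence[ImageVector], labels: Sequence):
    """In-sample AUC-ROC (binary) or confusion matrix (multiclass)."""
    X = np.vstack([v.normalized for v in vectors])
    y = np.asarray(labels)
    if model.n_classes == 2:
        p = model.estimator.predict_proba(X)[:, 1]
        return float(roc_auc_score(y == model.classes[1], p))
    pred = model.estimator.predict(X)
    return confusion_matrix(y, pred, labels=model.classes)


def cross_val_auc(
    vectors: Sequence[ImageVector],
    labels: Sequence,
    C: float = 1.0,
    n_folds: int = 5,
    seed: int = 0,
):
    """Stratified k-fold cross-validated AUC (binary) or confusion matrix.

    Probabilities are pooled across held-out folds before computing the rank
    statistic (or the confusion matrix for the multiclass case).
    """
    X = np.vstack([v.normalized for v in vectors])
    y = np.asarray(labels)
    classes = np.unique(y)
    clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-8, max_iter=5000)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = cross_val_predict(clf, X, y, cv=cv, method="predict_proba")
    if len(classes) == 2:
        return float(roc_auc_score(y == classes[1], proba[:, 1]))
    pred = classes[np.argmax(proba, axis=1)]
    return confusion_matrix(y, pred, labels=classes)


def attention_scores(
    model: ClassifierModel,
    image_vector: ImageVector,
    encodings: List[PatchEncoding],
    class_label=None,
    check_provenance: bool = True,
    use_abs: bool = True,
) -> AttentionMap:
    """Decompose the image-level linear score into per-patch attention scores.

    Word k contributes c_k = w_k * x_k (x the normalized TF-IDF vector); patch
    p receives sum_k c_k * |coeffs_p[k]| / sum_q |coeffs_q[k]|, words with zero
    total usage contributing nothing. The patch scores sum to sum_k w_k x_k
    exactly up to float roundoff.
    """
    if image_vector.normalized is None:
        raise ValueError("image vector has no normalized representation; apply TF-IDF first")
    C = np.vstack([e.coeffs for e in encodings])
    A = np.abs(C) if use_abs else np.clip(C, 0, None)
    usage = A.sum(axis=0)
    if check_provenance and image_vector.raw_usage.size:
        if not np.allclose(usage, image_vector.raw_usage, rtol=1e-8, atol=1e-10):
            raise ValueError(
                "encoding/vector provenance mismatch: pooled usage does not "
                "reproduce the image vector's raw usage"
            )
    w = model.weight_vector(class_label)
    contrib = w * image_vector.normalized  # c_k
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(usage > 0, contrib / usage, 0.0)
    patch_scores = A @ share
    return AttentionMap(patch_scores=patch_scores, image_id=image_vector.image_id)


def render_attention(
    volume_shape: tuple,
    patches: List[Patch],
    patch_scores: np.ndarray,
    mode: str = "uniform",
    positive_only: bool = False,
) -> AttentionMap:
    """Spread patch scores over their cubic supports into a volumetric map.

    Uniform mode assigns score / edge^3 to every voxel of the patch cube so
    the rendered map conserves the decomposed score exactly; Gaussian mode
    weights voxels by an isotropic Gaussian (sigma = edge/4) normalized to the
    same total. Overlapping patches accumulate additively. The ``rescaled``
    copy is per-image min-max normalized to [0, 1]; if all rendered values are
    equal it is all zeros (with a warning). ``positive_only`` drops patches
    with non-positive scores before rendering.
    """
    scores = np.asarray(patch_scores, dtype=np.float64)
    if len(patches) != scores.size:
        raise ValueError("one score per patch required")
    vol = np.zeros(volume_shape, dtype=np.float64)
    for patch, s in zip(patches, scores):
        if positive_only and s <= 0:
            continue
        sl = patch.slices
        if sl is None:
            raise ValueError("patch has no recorded volume location")
        for a, dim in zip(sl, volume_shape):
            if a.start < 0 or a.stop > dim:
                raise ValueError("patch outside volume bounds")
        n_vox = patch.edge_len ** 3
        if mode == "uniform":
            vol[sl] += s / n_vox
        elif mode == "gaussian":
            ax = np.arange(patch.edge_len) - patch.edge_len // 2
            g1 = np.exp(-(ax ** 2) / (2.0 * (patch.edge_len / 4.0) ** 2))
            g = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
            vol[sl] += s * g / g.sum()
        else:
            raise ValueError(f"unknown render mode {mode!r}")
    vmin, vmax = vol.min(), vol.max()
    if vmax > vmin:
        rescaled = (vol - vmin) / (vmax - vmin)
    else:
        warnings.warn("attention render is constant; rescaled map set to zeros")
        rescaled = np.zeros_like(vol)
    return AttentionMap(patch_scores=scores, volume_render=vol, rescaled=rescaled)
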