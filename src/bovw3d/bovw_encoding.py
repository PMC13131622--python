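"""Visual codebook learning, soft encoding, pooling and TF-IDF image vectors.

Descriptors pooled across the whole dataset are used to learn a K-word
codebook (default K = 200) by mini-batch sparse dictionary learning; each
descriptor is then soft-assigned, i.e. encoded as a sparse coefficient vector
over all K atoms rather than snapped to a single nearest word. Per image, the
absolute coefficients are summed into a word-usage vector ("term
frequencies"), reweighted by a smoothed inverse document frequency to
down-weight ubiquitous words, and L2-normalized. The normalization makes the
representation invariant to the number of keypoints per image (cell size).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.decomposition import MiniBatchDictionaryLearning, sparse_encode

#: presence threshold for document frequency and "zero usage"
PRESENCE_EPS = 1e-8


@dataclass
class Codebook:
    """K x D matrix of unit-norm visual words plus training metadata."""

    atoms: np.ndarray
    seed: int = 0
    alpha: float = 1.0
    n_iter: int = 1000

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2 or self.atoms.shape[0] < 2:
            raise ValueError("codebook needs a K x D matrix with K >= 2")

    @property
    def n_words(self) -> int:
        return self.atoms.shape[0]

    def to_json(self) -> dict:
        return {
            "schema": "bovw3d.codebook/1",
            "atoms": self.atoms.tolist(),
            "seed": self.seed,
            "alpha": self.alpha,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_json(cls, d: dict) -> "Codebook":
        return cls(atoms=np.array(d["atoms"]), seed=d["seed"], alpha=d["alpha"], n_iter=d["n_iter"])


@dataclass
class PatchEncoding:
    coeffs: np.ndarray
    keypoint_ref: object = None


@dataclass
class ImageVector:
    image_id: str
    raw_usage: np.ndarray
    tfidf: Optional[np.ndarray] = None
    normalized: Optional[np.ndarray] = None
    n_patches: int = 0


@dataclass
class TfidfModel:
    """Smoothed inverse-document-frequency weights: idf = ln((1+N)/(1+df)) + 1."""

    idf: np.ndarray
    n_documents: int
    presence_eps: float = PRESENCE_EPS

    def to_json(self) -> dict:
        return {
            "schema": "bovw3d.tfidf/1",
            "idf": self.idf.tolist(),
            "n_documents": self.n_documents,
            "presence_eps": self.presence_eps,
        }

    @classmethod
    def from_json(cls, d: dict) -> "TfidfModel":
        return cls(np.array(d["idf"]), d["n_documents"], d["presence_eps"])


def learn_codebook(
    descriptors: np.ndarray,
    K: int = 200,
    seed: int = 0,
    alpha: float = 1.0,
    n_iter: int = 1000,
) -> Codebook:
    """Learn K unit-norm visual words by mini-batch sparse dictionary learning.

    Descriptors must be pooled across all images of the dataset so the same
    vocabulary serves every stratum. Deterministic given the seed.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("descriptors must be an (n, D) matrix")
    if X.shape[0] < K:
        raise ValueError(
            f"{X.shape[0]} descriptors < K={K} words; use a smaller codebook"
        )
    learner = MiniBatchDictionaryLearning(
        n_components=K,
        alpha=alpha,
        max_iter=n_iter,
        random_state=seed,
        transform_algorithm="lasso_lars",
        transform_alpha=alpha,
    )
    learner.fit(X)
    atoms = learner.components_.copy()
    norms = np.linalg.norm(atoms, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    atoms[nz] /= norms[nz]
    # degenerate (all-zero) atoms are replaced by unit basis vectors so the
    # codebook invariant holds even if the learner under-uses components
    for i in np.nonzero(~nz)[0]:
        atoms[i, i % atoms.shape[1]] = 1.0
    return Codebook(atoms=atoms, seed=seed, alpha=alpha, n_iter=n_iter)


def encode_descriptors(
    cb: Codebook,
    descriptors: np.ndarray,
    alpha: float = None,
    keypoint_refs: Sequence = None,
) -> List[PatchEncoding]:
    """Soft-assign descriptors: sparse-coding coefficients over all K atoms.

    A zero descriptor encodes to the zero vector. Order preserving.
    """
    X = np.atleast_2d(np.asarray(descriptors, dtype=np.float64))
    if X.shape[1] != cb.atoms.shape[1]:
        raise ValueError(
            f"descriptor length {X.shape[1]} != atom length {cb.atoms.shape[1]}"
        )
    if alpha is None:
        alpha = cb.alpha * 0.1
    codes = sparse_encode(X, cb.atoms, algorithm="lasso_lars", alpha=alpha)
    refs = keypoint_refs if keypoint_refs is not None else [None] * X.shape[0]
    return [PatchEncoding(coeffs=c, keypoint_ref=r) for c, r in zip(codes, refs)]


def pool_image(
    encodings: List[PatchEncoding],
    image_id: str = "",
    use_abs: bool = True,
    n_words: int = None,
) -> ImageVector:
    """Sum patch coefficient vectors into a per-image word-usage vector.

    Sparse-coding coefficients may be negative; by default their absolute
    values are summed so the usage is a well-defined non-negative frequency
    (the quantity the TF-IDF reweighting and the attention redistribution
    presuppose). ``use_abs=False`` clips positive parts instead.
    """
    if not encodings:
        warnings.warn(f"image {image_id!r} has no accepted patches; zero vector")
        return ImageVector(image_id=image_id, raw_usage=np.zeros(n_words or 0), n_patches=0)
    C = np.vstack([e.coeffs for e in encodings])
    usage = np.abs(C).sum(axis=0) if use_abs else np.clip(C, 0, None).sum(axis=0)
    return ImageVector(image_id=image_id, raw_usage=usage, n_patches=len(encodings))


def fit_tfidf(raw_usages: Sequence[np.ndarray]) -> TfidfModel:
    """Fit smoothed IDF weights from a corpus of per-image usage vectors."""
    U = np.vstack(list(raw_usages))
    if U.shape[0] < 2:
        raise ValueError("TF-IDF needs at least 2 images")
    n = U.shape[0]
    df = (U > PRESENCE_EPS).sum(axis=0)
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    return TfidfModel(idf=idf, n_documents=n)


def apply_tfidf_l2(model: TfidfModel, iv: ImageVector) -> ImageVector:
    """TF-IDF reweight then L2-normalize one image vector (in place, returned).

    All-zero usage stays all-zero.
    """
    tf = iv.raw_usage * model.idf
    norm = np.linalg.norm(tf)
    iv.tfidf = tf
    iv.normalized = tf / norm if norm > 0 else tf.copy()
    return iv


def embed_2d(vectors: Sequence[ImageVector], seed: int = 0, **umap_kwargs) -> np.ndarray:
    """UMAP 2D embedding of the normalized image vectors (visualization only)."""
    X = np.vstack([v.normalized for v in vectors])
    if X.shape[0] < 4:
        raise ValueError("need at least 4 images to embed")
    import umap

    n_neighbors = min(umap_kwargs.pop("n_neighbors", 15), X.shape[0] - 1)
    reducer = umap.UMAP(n_components=2, random_state=seed, n_neighbors=n_neighbors, **umap_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reducer.fit_transform(X)
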