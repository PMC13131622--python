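"""High-attention blob and 3D Haralick texture quantification.

Attention maps are thresholded with one global threshold to mark
"high-attention" voxels; 3D connected-component labelling then yields the
number and voxel volume of isolated high-attention blobs per image. Texture
inside high-attention regions is characterized with 13 Haralick features of
the gray-level co-occurrence matrix (GLCM): intensities are clipped to the
1st-99th in-mask percentiles, rescaled and quantized to 32 gray levels with
background reserved as level 0, and co-occurrences are counted at distance 1
over the 13 unique 3D directions, ignoring any pair involving level 0,
symmetrized and normalized per direction; the 13 statistics are averaged over
directions with at least one valid pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

from .volume_io import Volume

N_GRAY_LEVELS = 32

HARALICK_FEATURE_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_corr_1",
    "info_measure_corr_2",
)

#: the 13 unique distance-1 offsets in 3D (one of each +/- pair)
GLCM_OFFSETS_3D = [
    (0, 0, 1),
    (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class BlobStats:
    image_id: str
    n_blobs: int
    blob_volumes: List[int]
    threshold: float

    def __post_init__(self):
        assert self.n_blobs == len(self.blob_volumes)


@dataclass
class HaralickVector:
    features: np.ndarray  # length 13, ordered as HARALICK_FEATURE_NAMES
    valid: bool = True
    degenerate: bool = False  # zero-variance patch: correlation/IMC defined 0
    patch_ref: object = None

    def as_dict(self) -> dict:
        return dict(zip(HARALICK_FEATURE_NAMES, self.features))


def threshold_attention(attention: np.ndarray, thresh: float) -> np.ndarray:
    """Boolean mask of voxels with attention strictly above the global threshold."""
    return np.asarray(attention) > thresh


def global_attention_threshold(maps: Sequence[np.ndarray], percentile: float = 90.0) -> float:
    """Dataset-wide threshold: the given percentile of positive voxel scores
    pooled over all maps (a reproducible stand-in for an empirical choice)."""
    pos = np.concatenate([m[m > 0].ravel() for m in maps]) if maps else np.array([])
    if pos.size == 0:
        return 0.0
    return float(np.percentile(pos, percentile))


def blob_analysis(mask: np.ndarray, connectivity: int = 26, image_id: str = "",
                  threshold: float = float("nan")) -> BlobStats:
    """Connected-component count and voxel volumes under 6/18/26-connectivity.

    Labelling follows scan order, so results are deterministic.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    volumes = np.bincount(labels.ravel())[1:].tolist() if n else []
    return BlobStats(image_id=image_id, n_blobs=n, blob_volumes=[int(v) for v in volumes],
                     threshold=threshold)


def quantize_for_texture(v: Volume, lo_pct: float = 1.0, hi_pct: float = 99.0,
                         n_levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Quantize in-mask intensities to integer levels 1..n_levels; background 0.

    In-mask values are clipped to the [lo, hi] percentile window (computed over
    in-mask voxels), rescaled to [0, 1] and mapped to levels 1..n_levels, with
    the top of the window landing exactly on the top level. Level 0 is reserved
    for background so co-occurrence counting can ignore it.
    """
    fg = v.foreground()
    data = np.asarray(v.data, dtype=np.float64)
    sel = data[fg]
    if sel.size == 0:
        return np.zeros(v.data.shape, dtype=np.uint8)
    p_lo, p_hi = np.percentile(sel, [lo_pct, hi_pct])
    out = np.zeros(v.data.shape, dtype=np.uint8)
    if p_lo == p_hi:
        warnings.warn("constant in-mask signal; all foreground set to level 1")
        out[fg] = 1
        return out
    norm = (np.clip(data, p_lo, p_hi) - p_lo) / (p_hi - p_lo)
    levels = np.minimum(np.floor(norm * n_levels).astype(np.int64) + 1, n_levels)
    out[fg] = levels[fg]
    return out


def _glcm_direction(q: np.ndarray, offset: Tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one offset; zeros ignored.

    Returns None when the direction has no valid (both nonzero) pair.
    """
    dz, dy, dx = offset
    nz, ny, nx = q.shape

    def rng(d, n):
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    (az, bz), (ay, by), (ax, bx) = rng(dz, nz), rng(dy, ny), rng(dx, nx)
    a = q[az, ay, ax].ravel()
    b = q[bz, by, bx].ravel()
    sel = (a > 0) & (b > 0)
    if not sel.any():
        return None
    a = a[sel].astype(np.int64) - 1
    b = b[sel].astype(np.int64) - 1
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T  # symmetrize
    return counts / counts.sum()


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _haralick_from_glcm(P: np.ndarray) -> Tuple[np.ndarray, bool]:
    """The 13 Haralick statistics of one normalized GLCM.

    Correlation and the two information measures of correlation are defined as
    0 on degenerate (zero-variance) matrices; the flag reports degeneracy.
    """
    n = P.shape[0]
    k = np.arange(n, dtype=np.float64)
    i, j = np.meshgrid(k, k, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(px @ k)
    uy = float(py @ k)
    vx = float(px @ (k ** 2)) - ux ** 2
    vy = float(py @ (k ** 2)) - uy ** 2

    # sum and difference distributions over i+j and |i-j|
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (i + j).astype(int).ravel(), P.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(i - j).astype(int).ravel(), P.ravel())
    ks = np.arange(2 * n - 1, dtype=np.float64)
    kd = np.arange(n, dtype=np.float64)

    asm = float((P ** 2).sum())
    contrast = float((kd ** 2) @ p_diff)
    degenerate = vx <= 0 or vy <= 0
    if degenerate:
        correlation = 0.0
    else:
        correlation = (float((i * j * P).sum()) - ux * uy) / np.sqrt(vx * vy)
    variance = vx
    idm = float((P / (1.0 + (i - j) ** 2)).sum())
    sum_avg = float(ks @ p_sum)
    sum_var = float((ks ** 2) @ p_sum) - sum_avg ** 2
    sum_ent = _entropy2(p_sum)
    entropy = _entropy2(P.ravel())
    mu_d = float(kd @ p_diff)
    diff_var = float((kd ** 2) @ p_diff) - mu_d ** 2
    diff_ent = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(P * log_pxy).sum())
    hxy2 = _entropy2(pxy.ravel())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    feats = np.array([
        asm, contrast, correlation, variance, idm, sum_avg, sum_var,
        sum_ent, entropy, diff_var, diff_ent, imc1, imc2,
    ])
    return feats, degenerate


def haralick_patch(qpatch: np.ndarray, n_levels: int = N_GRAY_LEVELS,
                   patch_ref=None) -> HaralickVector:
    """13 Haralick features of a quantized patch, averaged over 3D directions.

    Co-occurrences are counted at distance 1 over the 13 unique directions;
    pairs involving level 0 are excluded; each direction's matrix is
    symmetrized and normalized before feature computation; the average runs
    over directions with at least one valid pair. A patch yielding no valid
    pair in any direction is flagged invalid (and excluded from pooling).
    """
    q = np.asarray(qpatch)
    if q.ndim != 3:
        raise ValueError("quantized patch must be 3D")
    per_dir = []
    degenerate = False
    for off in GLCM_OFFSETS_3D:
        P = _glcm_direction(q, off, n_levels)
        if P is None:
            continue
        feats, degen = _haralick_from_glcm(P)
        degenerate = degenerate or degen
        per_dir.append(feats)
    if not per_dir:
        return HaralickVector(features=np.full(13, np.nan), valid=False, patch_ref=patch_ref)
    return HaralickVector(
        features=np.mean(per_dir, axis=0), valid=True, degenerate=degenerate,
        patch_ref=patch_ref,
    )


def pool_texture(
    patch_records: Sequence[Tuple[str, str, HaralickVector]],
    kde_grid_points: int = 200,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], np.ndarray]]:
    """Per-image feature means and per-condition kernel density estimates.

    ``patch_records`` holds (image_id, condition, HaralickVector) triples;
    invalid vectors are dropped. Returns a per-image mean table (one row per
    image with at least one valid patch) and per-(condition, feature) KDE
    curves evaluated on a common grid, as an (x, density) array. KDE bandwidth
    follows Scott's rule; densities are presentation-layer only.
    """
    rows = []
    for image_id, condition, hv in patch_records:
        if not hv.valid:
            continue
        rows.append({"image_id": image_id, "condition": condition,
                     **dict(zip(HARALICK_FEATURE_NAMES, hv.features))})
    if not rows:
        return pd.DataFrame(columns=["image_id", "condition", *HARALICK_FEATURE_NAMES]), {}
    df = pd.DataFrame(rows)
    per_image = df.groupby(["image_id", "condition"], as_index=False)[
        list(HARALICK_FEATURE_NAMES)
    ].mean()

    kdes: Dict[Tuple[str, str], np.ndarray] = {}
    for feat in HARALICK_FEATURE_NAMES:
        lo, hi = df[feat].min(), df[feat].max()
        if not np.isfinite(lo) or lo == hi:
            continue
        grid = np.linspace(lo, hi, kde_grid_points)
        for cond, sub in df.groupby("condition"):
            vals = sub[feat].to_numpy()
            if len(vals) < 2 or np.std(vals) == 0:
                continue
            kde = gaussian_kde(vals)  # Scott's rule by default
            kdes[(str(cond), feat)] = np.vstack([grid, kde(grid)])
    return per_image, kdes
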