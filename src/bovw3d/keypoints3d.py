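"""Multiscale 3D keypoint detection via a difference-of-Gaussians pyramid.

A 3D scale-space is built by blurring the normalized volume with isotropic
Gaussians at scales sigma in {1.0, 1.6, 2.2, 3.0} (voxel units) and
differencing successive levels; the cascade is repeated over three octaves,
each obtained by downsampling by two. Difference-of-Gaussians (DoG) volumes
approximate the Laplacian of Gaussian, whose extrema mark blob-like
structures. Candidates are strict local extrema in a 3x3x3 neighborhood whose
absolute response exceeds a contrast threshold; edge-like responses are
suppressed with a Hessian eigenvalue-ratio test, the 3D analogue of the SIFT
edge filter.

Sign convention: DoG = more-blurred minus less-blurred, so bright blobs are
DoG minima and dark blobs are DoG maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import Volume

#: minimum per-axis extent for an octave to be processed
_MIN_OCTAVE_EXTENT = 8


@dataclass
class ScaleSpaceConfig:
    sigmas: tuple = (1.0, 1.6, 2.2, 3.0)
    n_octaves: int = 3
    contrast_thresh: float = 0.01
    edge_ratio_thresh: float = 10.0

    def __post_init__(self):
        sig = tuple(float(s) for s in self.sigmas)
        if len(sig) < 2 or any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("sigmas must be strictly increasing with length >= 2")
        if self.n_octaves < 1:
            raise ValueError("n_octaves >= 1 required")
        if self.contrast_thresh < 0:
            raise ValueError("contrast_thresh must be non-negative")
        if self.edge_ratio_thresh <= 1:
            raise ValueError("edge_ratio_thresh must exceed 1")
        self.sigmas = sig


@dataclass
class DoGLevel:
    """One DoG volume: G(sigma_hi)*v - G(sigma_lo)*v at a given octave."""

    octave: int
    sigma_lo: float
    sigma_hi: float
    dog: np.ndarray


@dataclass
class DoGPyramid:
    levels: List[DoGLevel]
    original_shape: tuple
    config: ScaleSpaceConfig

    def at(self, octave: int, level: int) -> DoGLevel:
        for i, lv in enumerate(self.levels):
            if lv.octave == octave:
                return self.levels[i + level]
        raise KeyError(f"octave {octave} not in pyramid")


@dataclass
class Keypoint:
    """A scale-space extremum mapped back to original-resolution coordinates.

    ``sigma`` is the lower scale of the differenced pair; the effective scale
    at original resolution is ``sigma * 2**octave``.
    """

    position: tuple  # (z, y, x) at original resolution
    octave: int
    sigma: float
    response: float
    polarity: str  # "bright" (DoG minimum) or "dark" (DoG maximum)
    level: int = 0  # index of the DoG level within its octave

    @property
    def sigma_eff(self) -> float:
        return self.sigma * (2 ** self.octave)


def build_dog_pyramid(v: Volume, cfg: ScaleSpaceConfig = None) -> DoGPyramid:
    """Build the multiscale DoG pyramid of a normalized volume.

    Per octave, the base image is blurred at each configured sigma and
    successive blurs are differenced (more-blurred minus less-blurred). The
    next octave's base is the most-blurred level decimated by taking every
    second voxel. Octaves too small to support the kernels are skipped with a
    warning.
    """
    if cfg is None:
        cfg = ScaleSpaceConfig()
    base = np.asarray(v.data, dtype=np.float64)
    levels: List[DoGLevel] = []
    for octave in range(cfg.n_octaves):
        if min(base.shape) < _MIN_OCTAVE_EXTENT:
            warnings.warn(
                f"octave {octave} skipped: extent {base.shape} below minimal kernel support"
            )
            break
        blurred = [ndimage.gaussian_filter(base, sigma=s, mode="nearest") for s in cfg.sigmas]
        for i in range(len(cfg.sigmas) - 1):
            levels.append(
                DoGLevel(
                    octave=octave,
                    sigma_lo=cfg.sigmas[i],
                    sigma_hi=cfg.sigmas[i + 1],
                    dog=blurred[i + 1] - blurred[i],
                )
            )
        base = blurred[-1][::2, ::2, ::2]
    return DoGPyramid(levels=levels, original_shape=v.data.shape, config=cfg)


def _strict_extrema_masks(dog: np.ndarray):
    """Boolean masks of strict 26-neighborhood maxima / minima (interior only)."""
    foot = np.ones((3, 3, 3), dtype=bool)
    foot[1, 1, 1] = False
    # 'constant' padding with +/-inf would also exclude borders; we mask borders
    # explicitly because incomplete neighborhoods are defined as non-extremal.
    neigh_max = ndimage.maximum_filter(dog, footprint=foot, mode="nearest")
    neigh_min = ndimage.minimum_filter(dog, footprint=foot, mode="nearest")
    is_max = dog > neigh_max
    is_min = dog < neigh_min
    interior = np.zeros(dog.shape, dtype=bool)
    if all(s > 2 for s in dog.shape):
        interior[1:-1, 1:-1, 1:-1] = True
    return is_max & interior, is_min & interior


def detect_extrema(pyr: DoGPyramid, contrast_thresh: float = None) -> List[Keypoint]:
    """Strict 3x3x3 extrema above the contrast threshold, at original resolution.

    DoG minima are tagged ``bright``, maxima ``dark``. Octave coordinates are
    mapped back by multiplying by 2**octave. Border voxels (incomplete
    26-neighborhoods) are never extrema.
    """
    if contrast_thresh is None:
        contrast_thresh = pyr.config.contrast_thresh
    out: List[Keypoint] = []
    level_in_octave = {}
    for lv in pyr.levels:
        li = level_in_octave.get(lv.octave, 0)
        level_in_octave[lv.octave] = li + 1
        is_max, is_min = _strict_extrema_masks(lv.dog)
        scale = 2 ** lv.octave
        for mask, polarity in ((is_min, "bright"), (is_max, "dark")):
            zz, yy, xx = np.nonzero(mask)
            resp = lv.dog[zz, yy, xx]
            keep = np.abs(resp) > contrast_thresh
            for z, y, x, r in zip(zz[keep], yy[keep], xx[keep], resp[keep]):
                out.append(
                    Keypoint(
                        position=(int(z) * scale, int(y) * scale, int(x) * scale),
                        octave=lv.octave,
                        sigma=lv.sigma_lo,
                        response=float(r),
                        polarity=polarity,
                        level=li,
                    )
                )
    return out


def _hessian_3x3(dog: np.ndarray, z: int, y: int, x: int) -> np.ndarray:
    """Central-difference 3x3 Hessian of the DoG at an interior voxel."""
    d = dog
    H = np.empty((3, 3))
    c = 2.0 * d[z, y, x]
    H[0, 0] = d[z + 1, y, x] + d[z - 1, y, x] - c
    H[1, 1] = d[z, y + 1, x] + d[z, y - 1, x] - c
    H[2, 2] = d[z, y, x + 1] + d[z, y, x - 1] - c
    H[0, 1] = H[1, 0] = (
        d[z + 1, y + 1, x] - d[z + 1, y - 1, x] - d[z - 1, y + 1, x] + d[z - 1, y - 1, x]
    ) / 4.0
    H[0, 2] = H[2, 0] = (
        d[z + 1, y, x + 1] - d[z + 1, y, x - 1] - d[z - 1, y, x + 1] + d[z - 1, y, x - 1]
    ) / 4.0
    H[1, 2] = H[2, 1] = (
        d[z, y + 1, x + 1] - d[z, y + 1, x - 1] - d[z, y - 1, x + 1] + d[z, y - 1, x - 1]
    ) / 4.0
    return H


def edge_filter(
    pyr: DoGPyramid, kps: List[Keypoint], edge_ratio_thresh: float = None
) -> List[Keypoint]:
    """Discard edge-like keypoints via the Hessian eigenvalue anisotropy ratio.

    The 3x3 Hessian of the DoG is estimated by central differences at the
    keypoint's octave-resolution location; keypoints whose
    ``max|lambda| / min|lambda|`` exceeds the threshold are discarded, as are
    keypoints where the stencil does not fit (border) or the smallest
    eigenvalue vanishes (degenerate, treated as maximally edge-like). Order of
    survivors is preserved.
    """
    if edge_ratio_thresh is None:
        edge_ratio_thresh = pyr.config.edge_ratio_thresh
    by_key = {}
    counts = {}
    for lv in pyr.levels:
        idx = counts.get(lv.octave, 0)
        counts[lv.octave] = idx + 1
        by_key[(lv.octave, idx)] = lv.dog
    kept = []
    for kp in kps:
        dog = by_key.get((kp.octave, kp.level))
        if dog is None:
            continue
        scale = 2 ** kp.octave
        z, y, x = (p // scale for p in kp.position)
        if not all(1 <= c < s - 1 for c, s in zip((z, y, x), dog.shape)):
            continue
        lam = np.linalg.eigvalsh(_hessian_3x3(dog, z, y, x))
        amax, amin = np.abs(lam).max(), np.abs(lam).min()
        if amin == 0.0:
            continue
        if amax / amin <= edge_ratio_thresh:
            kept.append(kp)
    return kept


def detect_keypoints(v: Volume, cfg: ScaleSpaceConfig = None) -> List[Keypoint]:
    """Full detector: DoG pyramid -> 3x3x3 extrema -> contrast + edge filtering.

    Deterministic given (volume, config).
    """
    if cfg is None:
        cfg = ScaleSpaceConfig()
    pyr = build_dog_pyramid(v, cfg)
    kps = detect_extrema(pyr, cfg.contrast_thresh)
    return edge_filter(pyr, kps, cfg.edge_ratio_thresh)


def keypoints_to_frame(kps: List[Keypoint], image_id: str = "") -> pd.DataFrame:
    """Tabulate keypoints for CSV export."""
    return pd.DataFrame(
        {
            "image_id": image_id,
            "z": [k.position[0] for k in kps],
            "y": [k.position[1] for k in kps],
            "x": [k.position[2] for k in kps],
            "octave": [k.octave for k in kps],
            "sigma": [k.sigma for k in kps],
            "response": [k.response for k in kps],
            "polarity": [k.polarity for k in kps],
        }
    )
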