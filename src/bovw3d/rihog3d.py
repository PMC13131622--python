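"""Rotationally robust 3D histogram-of-oriented-gradients descriptors.

Plain 3D HOG bins absolute gradient orientations and so changes when the
structure rotates. Here every voxel's gradient is instead expressed relative
to its 26-connected neighbors: for a voxel p and neighbor q we accumulate the
relative orientation differences

    d_theta = theta_p - theta_q   wrapped to [0, pi]   (polar angle)
    d_phi   = phi_p  - phi_q      wrapped to [-pi, pi) (azimuth)

weighted by the relative magnitude ratio m_q / (m_p + eps), into a
(d_theta, d_phi) histogram. Because every quantity is defined against local
neighbors rather than the global frame, the descriptor is approximately
invariant to rigid rotations of the structure (exactly so for rotations about
the polar axis). The histogram is L2-normalized per patch, which together
with the magnitude ratio also makes it invariant to positive intensity
scaling.

Patch geometry follows the detector: a cubic patch of edge ~5 * sigma_eff
(rounded to odd) centered on the keypoint, accepted only when it lies fully
inside the volume and a sufficient fraction of its voxels fall inside the
mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Optional, Tuple

import numpy as np

from .keypoints3d import Keypoint
from .volume_io import Volume

EPS = 1e-8

#: the 26 offsets of a 3x3x3 neighborhood, centre excluded
NEIGHBOR_OFFSETS = [
    (dz, dy, dx)
    for dz, dy, dx in product((-1, 0, 1), repeat=3)
    if (dz, dy, dx) != (0, 0, 0)
]


@dataclass
class GradientField:
    """Per-voxel 3D gradient in spherical form.

    theta is the polar angle from the +z axis in [0, pi]; phi the azimuth
    atan2(g_y, g_x) in [-pi, pi). Zero-magnitude voxels get theta = phi = 0.
    """

    magnitude: np.ndarray
    theta: np.ndarray
    phi: np.ndarray


@dataclass
class Patch:
    center: Tuple[int, int, int]
    edge_len: int
    intensities: np.ndarray
    in_mask_fraction: float
    keypoint: Optional[Keypoint] = None
    slices: Optional[tuple] = None
    mask: Optional[np.ndarray] = None


@dataclass
class Descriptor:
    bins: np.ndarray
    keypoint_ref: Optional[Keypoint] = None


def compute_gradients(v: Volume) -> GradientField:
    """Finite-difference gradient field of a normalized volume.

    Central differences in the interior, one-sided at borders (numpy.gradient
    convention), returned as magnitude plus spherical angles.
    """
    data = np.asarray(v.data, dtype=np.float64)
    gz, gy, gx = np.gradient(data)
    mag = np.sqrt(gz * gz + gy * gy + gx * gx)
    ratio = np.zeros_like(mag)
    np.divide(gz, mag, out=ratio, where=mag > 0)
    theta = np.where(mag > 0, np.arccos(np.clip(ratio, -1.0, 1.0)), 0.0)
    phi = np.arctan2(gy, gx)
    phi = np.where(mag > 0, phi, 0.0)
    # atan2 returns +pi for (-x, 0) edge; fold to [-pi, pi)
    phi = np.where(phi >= np.pi, -np.pi, phi)
    return GradientField(magnitude=mag, theta=theta, phi=phi)


def round_to_odd(x: float) -> int:
    """Nearest odd integer >= 3 (even roundings bumped up)."""
    e = int(round(x))
    if e % 2 == 0:
        e += 1
    return max(e, 3)


def extract_patch(v: Volume, kp: Keypoint, min_mask_frac: float = 0.5) -> Optional[Patch]:
    """Cut the cubic patch around a keypoint, or reject it.

    Edge length is ``round_to_odd(5 * sigma_eff)``. The patch is rejected
    (None) when the cube does not fit inside the volume or when fewer than
    ``min_mask_frac`` of its voxels lie inside the mask. Without a mask the
    in-mask fraction is defined as 1.
    """
    edge = round_to_odd(5.0 * kp.sigma_eff)
    half = edge // 2
    z, y, x = kp.position
    lo = (z - half, y - half, x - half)
    hi = (z + half + 1, y + half + 1, x + half + 1)
    if any(a < 0 for a in lo) or any(b > s for b, s in zip(hi, v.data.shape)):
        return None
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    if v.mask is not None:
        sub = v.mask[sl] > 0
        frac = float(sub.mean())
        mask = sub
    else:
        frac = 1.0
        mask = None
    if frac < min_mask_frac:
        return None
    return Patch(
        center=(z, y, x),
        edge_len=edge,
        intensities=v.data[sl],
        in_mask_fraction=frac,
        keypoint=kp,
        slices=sl,
        mask=mask,
    )


def _wrap_dphi(dphi: np.ndarray) -> np.ndarray:
    return (dphi + np.pi) % (2.0 * np.pi) - np.pi


def rihog_descriptor(
    patch: Patch,
    grad: GradientField,
    n_theta: int = 4,
    n_phi: int = 8,
) -> Descriptor:
    """Relative-orientation gradient histogram for one accepted patch.

    For each in-patch, in-mask voxel p with gradient magnitude above eps and
    each of its in-patch 26-neighbors q, the weight m_q / (m_p + eps) is
    accumulated into the (|theta_p - theta_q|, wrap(phi_p - phi_q)) bin. The
    result is L2-normalized; an all-zero histogram (e.g. constant patch) is
    returned as zeros.
    """
    sl = patch.slices
    mag = grad.magnitude[sl]
    th = grad.theta[sl]
    ph = grad.phi[sl]
    hist = np.zeros((n_theta, n_phi), dtype=np.float64)
    e = patch.edge_len
    valid_p = mag > EPS
    if patch.mask is not None:
        valid_p = valid_p & patch.mask

    # bin geometry: d_theta in [0, pi], d_phi in [-pi, pi)
    t_scale = n_theta / np.pi
    p_scale = n_phi / (2.0 * np.pi)

    for dz, dy, dx in NEIGHBOR_OFFSETS:
        # overlap of the patch with itself shifted by the offset
        def sl_pair(d, n):
            if d >= 0:
                return slice(0, n - d), slice(d, n)
            return slice(-d, n), slice(0, n + d)

        (pz, qz), (py, qy), (px, qx) = (sl_pair(d, e) for d in (dz, dy, dx))
        m_p = mag[pz, py, px]
        m_q = mag[qz, qy, qx]
        sel = valid_p[pz, py, px]
        if not sel.any():
            continue
        dth = np.abs(th[pz, py, px] - th[qz, qy, qx])[sel]
        dph = _wrap_dphi((ph[pz, py, px] - ph[qz, qy, qx]))[sel]
        w = (m_q / (m_p + EPS))[sel]
        ti = np.minimum((dth * t_scale).astype(np.intp), n_theta - 1)
        pi_ = np.minimum(((dph + np.pi) * p_scale).astype(np.intp), n_phi - 1)
        np.add.at(hist, (ti, pi_), w)

    bins = hist.ravel()
    norm = np.linalg.norm(bins)
    if norm > 0:
        bins = bins / norm
    return Descriptor(bins=bins, keypoint_ref=patch.keypoint)


def describe_keypoints(
    v: Volume,
    kps: List[Keypoint],
    min_mask_frac: float = 0.5,
    n_theta: int = 4,
    n_phi: int = 8,
    grad: GradientField = None,
) -> Tuple[List[Patch], List[Descriptor]]:
    """Extract accepted patches around keypoints and compute their descriptors.

    The gradient field is computed once per volume at original resolution and
    shared across octaves.
    """
    if grad is None:
        grad = compute_gradients(v)
    patches, descs = [], []
    for kp in kps:
        patch = extract_patch(v, kp, min_mask_frac=min_mask_frac)
        if patch is None:
            continue
        patches.append(patch)
        descs.append(rihog_descriptor(patch, grad, n_theta=n_theta, n_phi=n_phi))
    return patches, descs
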