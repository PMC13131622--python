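"""Volume I/O, percentile normalization and single-cell cropping.

Volumes are single-channel 3D intensity grids in (z, y, x) axis order with
0-based voxel coordinates. An optional mask on the same grid carries either a
boolean foreground or integer cell labels. Intensities are normalized per
volume (per nucleus, when the volume is a single-cell crop) by clipping to a
percentile window and rescaling to [0, 1]; percentiles are computed over
in-mask voxels when a mask is present so that background does not dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile


@dataclass
class Volume:
    """A 3D scalar image with optional voxel spacing and mask.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Intensity grid.
    spacing : tuple of float, optional
        Physical voxel size per axis in micrometres, (z, y, x) order.
    mask : ndarray, optional
        Boolean or integer label grid with the same shape as ``data``.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self):
        return self.data.shape

    def foreground(self) -> np.ndarray:
        """Boolean foreground: mask > 0 when a mask exists, else all True."""
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask > 0


@dataclass
class NormalizationSpec:
    """Percentile window for intensity normalization (defaults 5th-95th)."""

    lo_pct: float = 5.0
    hi_pct: float = 95.0

    def __post_init__(self):
        if not (0.0 <= self.lo_pct < self.hi_pct <= 100.0):
            raise ValueError(
                f"require 0 <= lo_pct < hi_pct <= 100, got ({self.lo_pct}, {self.hi_pct})"
            )


def read_volume(path, mask_path=None) -> Volume:
    """Read a 3D TIFF / OME-TIFF stack as a :class:`Volume`.

    Single-channel 4D payloads (a singleton channel axis) are squeezed.
    Voxel spacing is taken from TIFF resolution / ImageJ metadata when
    available, else unit spacing.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = _spacing_from_tiff(tf)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"{path} does not contain a single-channel 3D stack (got {data.ndim}D after squeeze)"
        )
    mask = None
    if mask_path is not None:
        mask = np.squeeze(tifffile.imread(mask_path))
        if mask.ndim != 3:
            raise ValueError(f"mask {mask_path} is not 3D")
    return Volume(data=data, spacing=spacing, mask=mask)


def _spacing_from_tiff(tf) -> tuple:
    dz = dy = dx = 1.0
    try:
        ij = tf.imagej_metadata
        if ij and "spacing" in ij:
            dz = float(ij["spacing"])
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                dx = den / num
        if yres is not None:
            num, den = yres.value
            if num:
                dy = den / num
    except Exception:
        pass
    return (dz, dy, dx)


def write_volume(path, v: Volume, dtype=None) -> None:
    """Write a Volume's data (and mask, as ``<stem>_mask.tif`` if requested via path pair)."""
    data = v.data if dtype is None else v.data.astype(dtype)
    tifffile.imwrite(
        Path(path), data, imagej=True, photometric="minisblack",
        metadata={"spacing": v.spacing[0], "axes": "ZYX"},
    )


def normalize_volume(v: Volume, spec: NormalizationSpec = None) -> Volume:
    """Clip to the [lo, hi] percentile window and rescale to [0, 1].

    Percentiles are computed over in-mask voxels when a mask is present,
    otherwise over the whole grid. A constant region (p_lo == p_hi) yields an
    all-zeros volume with a warning rather than an error, so a batch over many
    crops does not abort on one degenerate cell.
    """
    if spec is None:
        spec = NormalizationSpec()
    data = np.asarray(v.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    sel = data[v.foreground()]
    p_lo, p_hi = np.percentile(sel, [spec.lo_pct, spec.hi_pct])
    if p_lo == p_hi:
        warnings.warn("constant region under normalization window; returning zeros")
        out = np.zeros_like(data)
    else:
        out = (np.clip(data, p_lo, p_hi) - p_lo) / (p_hi - p_lo)
    return replace(v, data=out)


def crop_to_label(v: Volume, label_id: int, pad: int = 0) -> Volume:
    """Extract the tight bounding box of one labelled cell (plus ``pad`` voxels).

    The crop's mask is the boolean footprint of ``label_id`` alone; other
    labels in the box become background. The crop origin (voxel offset into
    the parent volume) is returned on the ``origin`` attribute so original
    coordinates can be reconstructed exactly.
    """
    if v.mask is None:
        raise ValueError("crop_to_label requires a labelled mask")
    hit = v.mask == label_id
    if not hit.any():
        raise ValueError(f"label {label_id} not present in mask")
    idx = np.nonzero(hit)
    lo = [max(int(i.min()) - pad, 0) for i in idx]
    hi = [min(int(i.max()) + pad + 1, s) for i, s in zip(idx, v.data.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    out = Volume(data=v.data[sl].copy(), spacing=v.spacing, mask=hit[sl].copy())
    out.origin = tuple(lo)
    return out


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV (image_path, mask_path, label[, channel])."""
    df = pd.read_csv(path)
    required = {"image_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "mask_path" not in df.columns:
        df["mask_path"] = None
    return df
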