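"""Synthetic volumetric fixtures emulating the two study regimes.

Real acquisitions behind this pipeline (lattice light-sheet single-nucleus
crops; anisotropic confocal timelapse fields of view) are not redistributable,
so every stage is exercised on generated data with known ground truth:

* ellipsoidal "nuclei" whose interior texture differs between two classes —
  class A ("punctate"): many small, bright Gaussian blobs on a dim background,
  emulating punctate, heterogeneous chromatin-associated signal; class B
  ("smooth"): few large, low-amplitude blobs giving a smooth, homogeneous
  interior, emulating the smoother perturbed phenotype. Class B nuclei are
  optionally enlarged by a volume-shift factor, emulating the nuclear
  enlargement that accompanies the loss-of-function perturbation.
* a "timelapse" mode producing whole-FOV volumes with many overlapping cells,
  no masks, and axial downsampling by an anisotropy factor.

Generation is fully determined by the seed; ground truth (blob centers and
scales, nucleus volume) is recorded for localization and trend-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .volume_io import Volume, write_volume
import tifffile


@dataclass
class ClassTexture:
    """Interior texture parameters for one class."""

    n_blobs: int
    blob_sigma: float
    amplitude: float


@dataclass
class FixtureSpec:
    n_per_class: int = 20
    grid_shape: tuple = (48, 48, 48)
    nucleus_radius_mean: float = 16.0
    nucleus_radius_sd: float = 1.5
    class_a: ClassTexture = field(default_factory=lambda: ClassTexture(30, 1.6, 1.0))
    class_b: ClassTexture = field(default_factory=lambda: ClassTexture(4, 6.0, 0.6))
    noise_sigma: float = 0.05
    background: float = 0.1
    volume_shift_b: float = 1.5
    anisotropy: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1 or self.class_a.n_blobs < 1 or self.class_b.n_blobs < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class FixtureRecord:
    volume: Volume
    label: str
    image_id: str
    blob_centers: np.ndarray
    blob_sigma: float
    nucleus_volume: int


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _add_blob(data: np.ndarray, center, sigma: float, amplitude: float) -> None:
    """Add one isotropic Gaussian blob (evaluated on a 4-sigma support box)."""
    r = max(int(np.ceil(4 * sigma)), 2)
    lo = [max(int(c) - r, 0) for c in center]
    hi = [min(int(c) + r + 1, s) for c, s in zip(center, data.shape)]
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-d2 / (2.0 * sigma ** 2))


def make_nucleus(spec: FixtureSpec, class_id: str, seed: int) -> FixtureRecord:
    """Generate one masked ellipsoidal nucleus with class-specific texture.

    ``class_id`` is "A" (punctate) or "B" (smooth). Blob centers are sampled
    uniformly inside an eroded copy of the mask so all ground-truth centers lie
    strictly inside the nucleus. Intensities are blobs + background + Gaussian
    noise, clipped at 0.
    """
    if class_id not in ("A", "B"):
        raise ValueError("class_id must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    tex = spec.class_a if class_id == "A" else spec.class_b
    shape = spec.grid_shape
    center = tuple(s / 2.0 for s in shape)
    radius = rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd)
    radius = float(np.clip(radius, 4.0, min(shape) / 2.0 - 2.0))
    if class_id == "B":
        radius = min(radius * spec.volume_shift_b ** (1.0 / 3.0), min(shape) / 2.0 - 1.0)
    # mild ellipticity so nuclei are not perfect spheres
    ecc = rng.uniform(0.9, 1.1, size=3)
    radii = np.clip(radius * ecc, 3.0, min(shape) / 2.0 - 0.5)
    mask = _ellipsoid_mask(shape, center, radii)

    inner = _ellipsoid_mask(shape, center, radii * 0.75)
    candidates = np.argwhere(inner)
    if len(candidates) < tex.n_blobs:
        raise ValueError("blob count infeasible within mask interior")
    idx = rng.choice(len(candidates), size=tex.n_blobs, replace=False)
    centers = candidates[idx].astype(np.float64)

    data = np.zeros(shape, dtype=np.float64)
    for c in centers:
        _add_blob(data, c, tex.blob_sigma, tex.amplitude)
    data += spec.background
    data += rng.normal(0.0, spec.noise_sigma, size=shape)
    data = np.clip(data, 0.0, None)
    data[~mask] *= 0.05  # faint background outside the nucleus

    return FixtureRecord(
        volume=Volume(data=data, mask=mask.astype(np.uint8)),
        label=class_id,
        image_id=f"{class_id}_{seed}",
        blob_centers=centers,
        blob_sigma=tex.blob_sigma,
        nucleus_volume=int(mask.sum()),
    )


def make_dataset(spec: FixtureSpec, out_dir=None) -> Tuple[List[FixtureRecord], pd.DataFrame]:
    """Balanced two-class dataset of single-nucleus crops plus a manifest.

    When ``out_dir`` is given, volumes and masks are written as TIFF and the
    manifest as ``manifest.csv`` (columns image_path, mask_path, label,
    channel), matching the volume-IO contract; otherwise records stay in
    memory and the manifest carries empty paths.
    """
    records: List[FixtureRecord] = []
    rows = []
    base = np.random.SeedSequence(spec.seed).generate_state(2 * spec.n_per_class * 7)
    i = 0
    for class_id in ("A", "B"):
        for _ in range(spec.n_per_class):
            rec = make_nucleus(spec, class_id, seed=int(base[i] % (2 ** 31)))
            rec.image_id = f"{class_id}_{i:03d}"
            records.append(rec)
            row = {"image_path": "", "mask_path": "", "label": class_id,
                   "channel": 0, "image_id": rec.image_id,
                   "nucleus_volume": rec.nucleus_volume}
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                ip = out / f"{rec.image_id}.tif"
                mp = out / f"{rec.image_id}_mask.tif"
                write_volume(ip, rec.volume, dtype=np.float32)
                tifffile.imwrite(mp, rec.volume.mask.astype(np.uint8),
                                 photometric="minisblack")
                row["image_path"] = str(ip)
                row["mask_path"] = str(mp)
            rows.append(row)
            i += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return records, manifest


def make_timelapse_fov(
    spec: FixtureSpec, condition: str, seed: int, n_cells: int = 8,
    fov_shape: tuple = (64, 96, 96),
) -> FixtureRecord:
    """One anisotropic whole-FOV frame with many overlapping cells, no mask.

    Cells are ellipsoids with condition-dependent interior texture drawn from
    the class A/B parameters ("A*" conditions punctate, "B*" smooth); the
    volume is generated at near-isotropic resolution then axially decimated by
    the anisotropy factor, emulating coarse confocal z-sampling.
    """
    rng = np.random.default_rng(seed)
    tex = spec.class_a if condition.startswith("A") else spec.class_b
    data = np.zeros(fov_shape, dtype=np.float64)
    centers_all = []
    for _ in range(n_cells):
        c = [rng.uniform(0.2 * s, 0.8 * s) for s in fov_shape]
        radii = rng.uniform(8, 14, size=3)
        cell = _ellipsoid_mask(fov_shape, c, radii)
        inner = np.argwhere(_ellipsoid_mask(fov_shape, c, radii * 0.7))
        n_blobs = max(1, int(tex.n_blobs * cell.sum() / 10000))
        idx = rng.choice(len(inner), size=min(n_blobs, len(inner)), replace=False)
        for bc in inner[idx]:
            _add_blob(data, bc.astype(float), tex.blob_sigma, tex.amplitude)
            centers_all.append(bc)
        data[cell] += spec.background
    data += rng.normal(0.0, spec.noise_sigma, size=fov_shape)
    data = np.clip(data, 0.0, None)
    data = data[:: spec.anisotropy]  # coarse axial sampling
    return FixtureRecord(
        volume=Volume(data=data, spacing=(float(spec.anisotropy), 1.0, 1.0)),
        label=condition,
        image_id=f"fov_{condition}_{seed}",
        blob_centers=np.array(centers_all, dtype=float),
        blob_sigma=tex.blob_sigma,
        nucleus_volume=0,
    )


def make_timelapse_dataset(
    spec: FixtureSpec,
    conditions: tuple = ("A_pre", "A_post", "B_pre", "B_post"),
    n_per_condition: int = 6,
) -> Tuple[List[FixtureRecord], pd.DataFrame]:
    """Four-condition whole-FOV dataset (no masks) for the multiclass path.

    "pre" frames get halved blob amplitude relative to "post" frames of the
    same genotype, giving two scales of difference (strong pre/post contrast,
    subtler A/B texture contrast).
    """
    records: List[FixtureRecord] = []
    rows = []
    base = np.random.SeedSequence(spec.seed + 1).generate_state(len(conditions) * n_per_condition)
    i = 0
    for cond in conditions:
        cond_spec = spec
        if cond.endswith("_pre"):
            cond_spec = replace(
                spec,
                class_a=ClassTexture(spec.class_a.n_blobs // 2 + 1, spec.class_a.blob_sigma,
                                     spec.class_a.amplitude * 0.5),
                class_b=ClassTexture(spec.class_b.n_blobs, spec.class_b.blob_sigma,
                                     spec.class_b.amplitude * 0.5),
            )
        for _ in range(n_per_condition):
            rec = make_timelapse_fov(cond_spec, cond, seed=int(base[i] % (2 ** 31)))
            rec.image_id = f"fov_{cond}_{i:03d}"
            records.append(rec)
            rows.append({"image_path": "", "mask_path": "", "label": cond,
                         "channel": 0, "image_id": rec.image_id})
            i += 1
    return records, pd.DataFrame(rows)
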