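"""Model/Results surface for the full 3D bag-of-visual-words analysis.

:class:`BoVW3D` is constructed from a dataset (a manifest of TIFF volumes or
in-memory records plus condition labels) and a :class:`PipelineConfig`;
``fit()`` runs detection, description, codebook learning, encoding, pooling,
TF-IDF, classification and attention decomposition, and returns a
:class:`BoVW3DResults` carrying the learned codebook, image vectors,
classifier, cross-validated performance, attention maps, blob statistics and
texture tables, with a ``summary()`` report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import attention_analysis as aa
from . import bovw_encoding as bovw
from . import classify_interpret as ci
from . import keypoints3d as kp3
from . import rihog3d as rh
from .pipeline import PipelineConfig
from .volume_io import NormalizationSpec, Volume, normalize_volume, read_manifest, read_volume


class BoVW3D:
    """Interpretable 3D BoVW classification model for a labelled volume set.

    Parameters
    ----------
    volumes : sequence of Volume
        Single-channel 3D volumes (optionally masked).
    labels : sequence
        Per-volume condition labels.
    image_ids : sequence of str, optional
    config : PipelineConfig, optional
    """

    def __init__(self, volumes: Sequence[Volume], labels: Sequence, image_ids=None,
                 config: PipelineConfig = None):
        if len(volumes) != len(labels):
            raise ValueError("one label per volume required")
        self.volumes = list(volumes)
        self.labels = list(labels)
        self.image_ids = list(image_ids) if image_ids is not None else [
            f"img_{i:03d}" for i in range(len(volumes))
        ]
        self.config = config or PipelineConfig()

    @classmethod
    def from_manifest(cls, manifest, config: PipelineConfig = None) -> "BoVW3D":
        """Build from a manifest CSV / DataFrame (image_path, mask_path, label)."""
        df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
        vols, labels, ids = [], [], []
        for _, row in df.iterrows():
            mask_path = row.get("mask_path") or None
            if isinstance(mask_path, float) and np.isnan(mask_path):
                mask_path = None
            vols.append(read_volume(row["image_path"], mask_path=mask_path))
            labels.append(row["label"])
            ids.append(str(row.get("image_id", Path(str(row["image_path"])).stem)))
        return cls(vols, labels, image_ids=ids, config=config)

    @classmethod
    def from_records(cls, records, config: PipelineConfig = None) -> "BoVW3D":
        """Build from synthetic fixture records (or any objects with
        ``volume``, ``label`` and ``image_id`` attributes)."""
        return cls(
            [r.volume for r in records],
            [r.label for r in records],
            image_ids=[r.image_id for r in records],
            config=config,
        )

    # ------------------------------------------------------------------ fit

    def fit(self) -> "BoVW3DResults":
        cfg = self.config
        norm_spec = NormalizationSpec(cfg.lo_pct, cfg.hi_pct)
        ss_cfg = kp3.ScaleSpaceConfig(
            sigmas=cfg.sigmas, n_octaves=cfg.n_octaves,
            contrast_thresh=cfg.contrast_thresh, edge_ratio_thresh=cfg.edge_ratio_thresh,
        )

        normalized: List[Volume] = []
        keypoints: List[list] = []
        patches: List[list] = []
        descriptors: List[np.ndarray] = []
        for vid, vol in zip(self.image_ids, self.volumes):
            try:
                nv = normalize_volume(vol, norm_spec)
                kps = kp3.detect_keypoints(nv, ss_cfg)
                pats, descs = rh.describe_keypoints(
                    nv, kps, min_mask_frac=cfg.min_mask_frac,
                    n_theta=cfg.n_theta, n_phi=cfg.n_phi,
                )
            except Exception as e:  # re-raise with stage + image context
                raise RuntimeError(f"feature extraction failed for image {vid!r}") from e
            normalized.append(nv)
            keypoints.append(kps)
            patches.append(pats)
            descriptors.append(
                np.vstack([d.bins for d in descs]) if descs
                else np.zeros((0, cfg.n_theta * cfg.n_phi))
            )

        pooled = np.vstack(descriptors)
        codebook = bovw.learn_codebook(
            pooled, K=cfg.n_words, seed=cfg.seed, alpha=cfg.dict_alpha, n_iter=cfg.dict_iters
        )

        encodings: List[list] = []
        vectors: List[bovw.ImageVector] = []
        for vid, D in zip(self.image_ids, descriptors):
            encs = (
                bovw.encode_descriptors(codebook, D, alpha=cfg.encode_alpha)
                if len(D) else []
            )
            encodings.append(encs)
            vectors.append(
                bovw.pool_image(encs, image_id=vid, use_abs=cfg.pool_abs,
                                n_words=codebook.n_words)
            )

        tfidf = bovw.fit_tfidf([v.raw_usage for v in vectors])
        for v in vectors:
            bovw.apply_tfidf_l2(tfidf, v)

        embedding = None
        if len(vectors) >= 4:
            try:
                embedding = bovw.embed_2d(vectors, seed=cfg.seed)
            except Exception as e:
                warnings.warn(f"UMAP embedding skipped: {e}")

        classifier = ci.train_classifier(vectors, self.labels, C=cfg.C, seed=cfg.seed)
        if cfg.in_sample:
            performance = ci.evaluate_auc(classifier, vectors, self.labels)
        else:
            performance = ci.cross_val_auc(
                vectors, self.labels, C=cfg.C, n_folds=cfg.n_folds, seed=cfg.seed
            )

        # attention decomposition + rendering
        attention_maps: List[ci.AttentionMap] = []
        for vid, vol, vec, encs, pats, label in zip(
            self.image_ids, normalized, vectors, encodings, patches, self.labels
        ):
            if not encs:
                attention_maps.append(ci.AttentionMap(
                    patch_scores=np.zeros(0), volume_render=np.zeros(vol.shape),
                    rescaled=np.zeros(vol.shape), image_id=vid))
                continue
            amap = ci.attention_scores(
                classifier, vec, encs,
                class_label=label if classifier.n_classes > 2 else None,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rendered = ci.render_attention(
                    vol.shape, pats, amap.patch_scores, mode=cfg.render_mode,
                    positive_only=cfg.attention_positive_only,
                )
            rendered.image_id = vid
            attention_maps.append(rendered)

        # one global threshold across the dataset
        if cfg.attention_threshold is not None:
            thresh = float(cfg.attention_threshold)
        else:
            thresh = aa.global_attention_threshold(
                [m.rescaled for m in attention_maps], percentile=cfg.attention_percentile
            )

        blob_stats: List[aa.BlobStats] = []
        high_masks: List[np.ndarray] = []
        for vid, amap in zip(self.image_ids, attention_maps):
            hmask = aa.threshold_attention(amap.rescaled, thresh)
            high_masks.append(hmask)
            blob_stats.append(
                aa.blob_analysis(hmask, connectivity=cfg.blob_connectivity,
                                 image_id=vid, threshold=thresh)
            )

        # Haralick texture of high-attention patches: reuse the keypoint patch
        # geometry for patches whose centers fall in high-attention voxels.
        texture_records = []
        for vid, label, nv, pats, hmask in zip(
            self.image_ids, self.labels, normalized, patches, high_masks
        ):
            qvol = aa.quantize_for_texture(
                nv, lo_pct=cfg.texture_lo_pct, hi_pct=cfg.texture_hi_pct,
                n_levels=cfg.texture_levels,
            )
            for patch in pats:
                if not hmask[patch.center]:
                    continue
                hv = aa.haralick_patch(qvol[patch.slices], n_levels=cfg.texture_levels,
                                       patch_ref=patch)
                if hv.valid:
                    texture_records.append((vid, str(label), hv))
        texture_per_image, texture_kdes = aa.pool_texture(texture_records)

        return BoVW3DResults(
            model=self,
            config=cfg,
            normalized=normalized,
            keypoints=keypoints,
            patches=patches,
            descriptors=descriptors,
            codebook=codebook,
            encodings=encodings,
            vectors=vectors,
            tfidf=tfidf,
            embedding=embedding,
            classifier=classifier,
            performance=performance,
            attention_maps=attention_maps,
            attention_threshold=thresh,
            blob_stats=blob_stats,
            texture_records=texture_records,
            texture_per_image=texture_per_image,
            texture_kdes=texture_kdes,
        )


@dataclass
class BoVW3DResults:
    """Fitted artifacts of one pipeline run."""

    model: BoVW3D
    config: PipelineConfig
    normalized: List[Volume]
    keypoints: List[list]
    patches: List[list]
    descriptors: List[np.ndarray]
    codebook: bovw.Codebook
    encodings: List[list]
    vectors: List[bovw.ImageVector]
    tfidf: bovw.TfidfModel
    embedding: Optional[np.ndarray]
    classifier: ci.ClassifierModel
    performance: object  # float AUC (binary) or confusion matrix (multiclass)
    attention_maps: List[ci.AttentionMap]
    attention_threshold: float
    blob_stats: List[aa.BlobStats]
    texture_records: list
    texture_per_image: pd.DataFrame
    texture_kdes: dict

    # ------------------------------------------------------------- accessors

    @property
    def labels(self):
        return self.model.labels

    @property
    def image_ids(self):
        return self.model.image_ids

    @property
    def auc(self) -> float:
        if self.classifier.n_classes != 2:
            raise AttributeError("AUC is defined for the binary model; see .performance")
        return float(self.performance)

    def vectors_frame(self) -> pd.DataFrame:
        K = self.codebook.n_words
        rows = []
        for vid, label, v in zip(self.image_ids, self.labels, self.vectors):
            row = {"image_id": vid, "label": label, "n_patches": v.n_patches}
            row.update({f"w{k:03d}": v.normalized[k] for k in range(K)})
            rows.append(row)
        return pd.DataFrame(rows)

    def blob_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"image_id": b.image_id, "label": lab, "n_blobs": b.n_blobs,
             "total_blob_volume": int(sum(b.blob_volumes)),
             "mean_blob_volume": float(np.mean(b.blob_volumes)) if b.blob_volumes else 0.0,
             "threshold": b.threshold}
            for b, lab in zip(self.blob_stats, self.labels)
        ])

    def texture_class_means(self) -> pd.DataFrame:
        """Per-condition means of the per-image Haralick means."""
        if self.texture_per_image.empty:
            return self.texture_per_image
        return self.texture_per_image.groupby("condition")[
            list(aa.HARALICK_FEATURE_NAMES)
        ].mean()

    # --------------------------------------------------------------- summary

    def summary(self) -> str:
        lines = []
        n = len(self.image_ids)
        classes = self.classifier.classes
        lines.append("3D Bag-of-Visual-Words results")
        lines.append("=" * 34)
        lines.append(f"images: {n}  classes: {list(classes)}")
        n_kp = [len(k) for k in self.keypoints]
        n_pat = [len(p) for p in self.patches]
        lines.append(f"keypoints/image: mean {np.mean(n_kp):.1f} (min {min(n_kp)}, max {max(n_kp)})")
        lines.append(f"accepted patches/image: mean {np.mean(n_pat):.1f}")
        lines.append(f"codebook: {self.codebook.n_words} words x {self.codebook.atoms.shape[1]} dims")
        protocol = "in-sample" if self.config.in_sample else f"{self.config.n_folds}-fold CV"
        if self.classifier.n_classes == 2:
            lines.append(f"AUC-ROC ({protocol}): {float(self.performance):.3f}")
        else:
            lines.append(f"confusion matrix ({protocol}):")
            lines.append(str(np.asarray(self.performance)))
        lines.append(f"attention threshold (global): {self.attention_threshold:.4g}")
        bf = self.blob_frame()
        if not bf.empty:
            for lab, sub in bf.groupby("label"):
                lines.append(
                    f"  {lab}: mean {sub['n_blobs'].mean():.1f} high-attention blobs, "
                    f"mean blob volume {sub['mean_blob_volume'].mean():.1f} vox"
                )
        tm = self.texture_class_means()
        if not tm.empty:
            lines.append("high-attention texture (per-condition means):")
            for cond, row in tm.iterrows():
                lines.append(
                    f"  {cond}: contrast {row['contrast']:.3f}, "
                    f"IDM {row['inverse_difference_moment']:.3f}, "
                    f"entropy {row['entropy']:.3f}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------ save

    def save(self, out_dir) -> None:
        """Write the results bundle: tables as CSV, models as JSON, maps as TIFF."""
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_json(out / "config.json")
        (out / "codebook.json").write_text(json.dumps(self.codebook.to_json()))
        (out / "tfidf.json").write_text(json.dumps(self.tfidf.to_json()))
        (out / "classifier.json").write_text(json.dumps({
            "schema": "bovw3d.classifier/1",
            "weights": np.asarray(self.classifier.weights).tolist(),
            "intercept": np.asarray(self.classifier.intercept).tolist(),
            "classes": [str(c) for c in self.classifier.classes],
            "C": self.classifier.C,
        }))
        self.vectors_frame().to_csv(out / "vectors.csv", index=False)
        self.blob_frame().to_csv(out / "blob_stats.csv", index=False)
        self.texture_per_image.to_csv(out / "texture_per_image.csv", index=False)
        kp_rows = []
        for vid, kps in zip(self.image_ids, self.keypoints):
            kp_rows.append(kp3.keypoints_to_frame(kps, image_id=vid))
        pd.concat(kp_rows, ignore_index=True).to_csv(out / "keypoints.csv", index=False)
        if self.embedding is not None:
            pd.DataFrame({
                "image_id": self.image_ids, "label": self.labels,
                "umap_1": self.embedding[:, 0], "umap_2": self.embedding[:, 1],
            }).to_csv(out / "embedding.csv", index=False)
        maps_dir = out / "attention_maps"
        maps_dir.mkdir(exist_ok=True)
        for vid, amap in zip(self.image_ids, self.attention_maps):
            tifffile.imwrite(maps_dir / f"{vid}_attention.tif",
                             amap.volume_render.astype(np.float32),
                             photometric="minisblack")
        kde_rows = []
        for (cond, feat), curve in self.texture_kdes.items():
            kde_rows.append(pd.DataFrame({
                "condition": cond, "feature": feat,
                "grid": curve[0], "density": curve[1],
            }))
        if kde_rows:
            pd.concat(kde_rows, ignore_index=True).to_csv(out / "texture_kdes.csv", index=False)
        (out / "report.txt").write_text(self.summary() + "\n")
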