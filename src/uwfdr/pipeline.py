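"""End-to-end orchestration: image -> landmarks -> alignment -> crop -> score.

Each image is processed independently and yields either a complete record or
a failure record naming the first failing stage; one bad image never aborts
the batch.  Records carry the full geometry (landmarks, transform, crop
windows) needed to reproduce every crop exactly.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import imageio.v3 as iio
import numpy as np

from . import field_geometry as fg
from . import landmarks as lmk
from .errors import UwfdrError
from .types import LandmarkSet

log = logging.getLogger("uwfdr")

STAGES = ("read", "landmarks", "align", "crop", "score")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``unet_checkpoint`` switches disc segmentation from the heuristic
    (thresholded-blob ellipse fit) to the trained segmenter;
    ``classifier_checkpoint`` enables scoring.  Either may be None, in which
    case the corresponding stage is skipped or replaced by the heuristic.
    """

    landmark_config: lmk.LandmarkConfig = field(default_factory=lmk.LandmarkConfig)
    landmark_stats: Optional[lmk.ThresholdStats] = None
    unet_checkpoint: Optional[str] = None
    classifier_checkpoint: Optional[str] = None
    field_geometry: fg.FieldGeometryConfig = field(default_factory=fg.FieldGeometryConfig)
    field_kind: str = "SF7"
    apply_occlusion_qc: bool = True
    seed: int = 0
    out_dir: Optional[str] = None

    def config_hash(self) -> str:
        payload = {
            "landmark_config": asdict(self.landmark_config),
            "stats": ([self.landmark_stats.mu, self.landmark_stats.sigma]
                      if self.landmark_stats else None),
            "unet": self.unet_checkpoint,
            "classifier": self.classifier_checkpoint,
            "geometry": asdict(self.field_geometry),
            "kind": self.field_kind,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ImageRecord:
    image_id: str
    ok: bool
    failure_stage: Optional[str] = None
    failure_reason: Optional[str] = None
    landmarks: Optional[dict] = None
    transform: Optional[dict] = None
    crop_window: Optional[list] = None
    crop_path: Optional[str] = None
    qc_occluded: Optional[bool] = None
    score: Optional[float] = None
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _detect(image: np.ndarray, config: PipelineConfig) -> LandmarkSet:
    if config.landmark_stats is None:
        raise UwfdrError("pipeline requires landmark_stats (reference threshold)")
    if config.unet_checkpoint is None:
        return lmk.detect_landmarks(image, config.landmark_stats, config.landmark_config)
    # segmenter-backed mode: candidates -> best patch -> ellipse fit in patch space
    from . import od_unet as odu
    model = odu.SegModel.load(config.unet_checkpoint)
    cands = lmk.find_candidates(image, config.landmark_stats, config=config.landmark_config)
    if not cands:
        raise UwfdrError("no optic-disc candidate survived filtering")
    diameter = max(32, int(round(614 * lmk.native_scale(image.shape))))
    patches = [lmk.crop_candidate(image, c.fused_center, diameter, model.config.input_size)
               for c in cands]
    idx, mask = odu.select_best_candidate(model, patches)
    center, axes, angle = lmk.fit_ellipse(mask)
    # map patch-space geometry back to image coordinates
    ratio = diameter / model.config.input_size
    cr, cc = cands[idx].fused_center
    r0 = round(cr) - diameter // 2
    c0 = round(cc) - diameter // 2
    disc_center = (r0 + center[0] * ratio, c0 + center[1] * ratio)
    cfg_s = config.landmark_config.scaled(image.shape)
    macula = lmk.detect_macula(image, disc_center, cfg_s.macula_h_range,
                               cfg_s.macula_v_range, cfg_s.disc_exclusion_radius,
                               cfg_s.k_polarity)
    return LandmarkSet(disc_center=disc_center,
                       disc_axes=(axes[0] * ratio, axes[1] * ratio),
                       disc_angle=angle, macula_center=macula)


def run_pipeline(image_paths: Sequence, config: PipelineConfig) -> List[ImageRecord]:
    """Process a batch; returns one record per input, never raises per-image."""
    records: List[ImageRecord] = []
    chash = config.config_hash()
    cls_model = None
    if config.classifier_checkpoint is not None:
        from . import classifier as clf
        cls_model = clf.ClsModel.load(config.classifier_checkpoint)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        (out_dir / "crops").mkdir(parents=True, exist_ok=True)

    for path in image_paths:
        image_id = Path(str(path)).stem if not isinstance(path, np.ndarray) else f"array{len(records)}"
        rec = ImageRecord(image_id=image_id, ok=False, config_hash=chash)
        records.append(rec)
        stage = "read"
        try:
            if isinstance(path, np.ndarray):
                image = path
            else:
                image = iio.imread(path)
                if image.ndim == 3 and image.shape[2] == 4:
                    image = image[..., :3]
            stage = "landmarks"
            lm = _detect(image, config)
            rec.landmarks = lm.to_dict()
            stage = "align"
            img2, lm2, flipped = fg.normalize_laterality(image, lm)
            rotated, lm3, transform = fg.align_rotation(img2, lm2)
            transform.flipped = flipped
            rec.transform = transform.to_dict()
            stage = "crop"
            crop = fg.extract_field_crop(rotated, lm3, config.field_kind,
                                         config.field_geometry)
            rec.crop_window = list(crop.source_window)
            rec.qc_occluded = fg.flag_occlusion(crop) if config.apply_occlusion_qc else None
            if out_dir:
                crop_path = out_dir / "crops" / f"{image_id}_{config.field_kind.lower()}.png"
                iio.imwrite(crop_path, crop.image)
                rec.crop_path = str(crop_path)
            stage = "score"
            if cls_model is not None:
                from . import classifier as clf
                rec.score = float(clf.predict_scores(cls_model, [crop])[0])
            rec.ok = True
            rec.failure_stage = None
            log.info("pipeline ok image=%s", image_id)
        except Exception as exc:  # noqa: BLE001 - per-image isolation is the contract
            rec.ok = False
            rec.failure_stage = stage
            rec.failure_reason = str(exc)
            log.info("pipeline fail image=%s stage=%s reason=%s", image_id, stage, exc)

    n_ok = sum(r.ok for r in records)
    log.info("pipeline done: %d/%d complete", n_ok, len(records))
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "records.jsonl", "w") as fh:
            for rec in records:
                fh.write(rec.to_json() + "\n")
    return records
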