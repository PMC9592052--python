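"""End-to-end pipeline: simulate/load -> preprocess -> segment -> quantify.

One :class:`PipelineConfig` drives a reproducible run that writes
per-ROI and per-class CSV tables, predicted label masks, a log, and a
provenance manifest from which the identical run can be repeated.
Quantification always operates on the average z-projection; maximum
projection is reserved for display and kymographs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .classes import CLASS_NAMES, LabelImage
from .quantify import quantify_image, summarize
from .scene import (
    OpticsNoiseModel,
    SceneConfig,
    generate_dataset,
    generate_dataset_from_manifest,
)
from .segmentation import (
    ThresholdParams,
    detect_cells,
    merge_class_maps,
    refine_ring_fragments,
    threshold_segment,
    train_two_channel_classifiers,
)
from .stack_io import project, read_stack, register_channels

logger = logging.getLogger("tpmquant.pipeline")

_TUPLE_KEYS_SCENE = (
    "field_size_px", "clump_size_range", "cell_length_range_um",
    "patches_per_cell", "patch_amplitude_range", "cables_per_cell",
    "cable_amplitude_range", "ring_amplitude_range", "outside_photons",
)


@dataclass
class PipelineConfig:
    """All stage parameters of one run, with spec-level defaults."""

    # input: either a directory of image/label TIFFs with a manifest, or
    # inline generator settings (scene + optics + n_images)
    input_dir: str | None = None
    scene: SceneConfig = field(default_factory=SceneConfig)
    optics: OpticsNoiseModel = field(default_factory=OpticsNoiseModel)
    n_images: int = 12
    # channel roles: index of each channel in the stack
    channel_factin: int = 0
    channel_tpm: int = 1
    # stage parameters
    projection_mode: str = "average"
    register: bool = False
    max_shift_px: float = 10.0
    bleach_mode: str | None = None
    segmentation: str = "ground_truth"  # ground_truth | trained | threshold
    annotation_fraction: float = 0.02
    n_train_images: int = 2
    trim_fraction: float = 0.10
    erode_cables: bool = True
    min_structure_area_px: int = 5
    min_cell_area_px: int = 500
    clump_area_factor: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if self.channel_factin == self.channel_tpm:
            raise ValueError(
                "channel roles must be distinct: channel_factin == channel_tpm "
                f"== {self.channel_factin}"
            )
        if self.segmentation not in ("ground_truth", "trained", "threshold"):
            raise ValueError(f"unknown segmentation mode {self.segmentation!r}")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sc = dict(d.pop("scene", {}))
        for k in _TUPLE_KEYS_SCENE:
            if k in sc:
                sc[k] = tuple(sc[k])
        d["scene"] = SceneConfig(**sc)
        d["optics"] = OpticsNoiseModel(**d.pop("optics", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _train_classifiers(images, gt_labels, cfg: PipelineConfig):
    """Fit the classifier pair on sparse annotations subsampled from
    dense ground truth (synthetic-data stand-in for interactive
    annotation)."""
    clf_factin, clf_tpm = train_two_channel_classifiers(
        [proj.channel(cfg.channel_factin) for proj in images],
        [proj.channel(cfg.channel_tpm) for proj in images],
        [gt.labels for gt in gt_labels],
        seed=cfg.seed,
        annotation_fraction=cfg.annotation_fraction,
    )
    logger.info(
        "trained classifiers: holdout accuracy factin=%.3f tpm=%.3f",
        clf_factin.holdout_accuracy_,
        clf_tpm.holdout_accuracy_,
    )
    return clf_factin, clf_tpm


def _segment(proj, gt, cfg, classifiers) -> LabelImage:
    if cfg.segmentation == "ground_truth":
        if gt is None:
            raise ValueError("ground_truth segmentation requires label images")
        return gt
    if cfg.segmentation == "trained":
        clf_factin, clf_tpm = classifiers
        fmap = clf_factin.predict(proj.channel(cfg.channel_factin))
        tmap = clf_tpm.predict(proj.channel(cfg.channel_tpm))
        return refine_ring_fragments(merge_class_maps(fmap, tmap))
    fmap = threshold_segment(
        proj.channel(cfg.channel_factin),
        ThresholdParams(classes=("outside", "cytoplasm", "patch")),
    )
    tmap = threshold_segment(
        proj.channel(cfg.channel_tpm),
        ThresholdParams(classes=("outside", "cytoplasm", "cable", "ring")),
    )
    return refine_ring_fragments(merge_class_maps(fmap, tmap))


def _load_dataset(input_dir: Path):
    manifest = json.loads((input_dir / "manifest.json").read_text())
    stacks, gts = [], []
    for entry in manifest["files"]:
        stacks.append(read_stack(input_dir / entry["image"]))
        lbl_path = input_dir / entry.get("labels", "")
        if entry.get("labels") and lbl_path.exists():
            gts.append(LabelImage(tifffile.imread(lbl_path)))
        else:
            gts.append(None)
    return stacks, gts


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full run and return the output directory.

    Stage order: (simulate) -> average projection -> registration ->
    segmentation -> cell detection -> ROI quantification -> aggregation.
    Any stage error halts the run naming the stage; partial outputs are
    retained in the run directory.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        if config.input_dir is None:
            stage = "simulate"
            data_dir = out_dir / "data"
            # extra leading images are reserved for classifier training
            n_total = config.n_images + (
                config.n_train_images if config.segmentation == "trained" else 0
            )
            generate_dataset(config.scene, config.optics, n_total, data_dir, config.seed)
        else:
            data_dir = Path(config.input_dir)
        stage = "load"
        stacks, gts = _load_dataset(data_dir)

        stage = "projection"
        projections = [project(s, mode="average") for s in stacks]

        stage = "registration"
        valid_masks = [None] * len(projections)
        if config.register:
            for i, proj in enumerate(projections):
                res = register_channels(
                    proj.channel(config.channel_factin),
                    proj.channel(config.channel_tpm),
                    max_shift=config.max_shift_px,
                )
                proj.data[config.channel_tpm] = res.aligned
                valid_masks[i] = res.valid_mask
                logger.info("image %d: channel shift %s", i, res.shift.tolist())

        stage = "segmentation"
        classifiers = None
        first = 0
        if config.segmentation == "trained":
            if config.input_dir is None:
                first = config.n_train_images
                classifiers = _train_classifiers(
                    projections[:first], gts[:first], config
                )
            else:
                classifiers = _train_classifiers(
                    projections[: config.n_train_images],
                    gts[: config.n_train_images],
                    config,
                )
                first = config.n_train_images
        labels = [
            _segment(projections[i], gts[i], config, classifiers)
            for i in range(first, len(projections))
        ]
        projections = projections[first:]
        valid_masks = valid_masks[first:]

        stage = "cell_detection"
        cells_per_image = [
            detect_cells(
                lab,
                min_area=config.min_cell_area_px,
                clump_area_factor=config.clump_area_factor,
            )
            for lab in labels
        ]
        n_clumps = sum(c.is_clump for cells in cells_per_image for c in cells)
        logger.info(
            "detected %d instances, %d flagged as clumps",
            sum(len(c) for c in cells_per_image),
            n_clumps,
        )

        stage = "quantification"
        tables = []
        for i, (proj, lab, cells) in enumerate(
            zip(projections, labels, cells_per_image)
        ):
            tifffile.imwrite(out_dir / f"mask_{i:03d}.tif", lab.labels)
            tables.append(
                quantify_image(
                    proj,
                    lab,
                    cells,
                    channel_roles={
                        "factin": config.channel_factin,
                        "tpm": config.channel_tpm,
                    },
                    trim_fraction=config.trim_fraction,
                    erode_cables=config.erode_cables,
                    min_structure_area_px=config.min_structure_area_px,
                    valid_mask=valid_masks[i],
                    image_name=f"image_{i:03d}",
                )
            )
        roi_table = pd.concat(tables, ignore_index=True)
        excluded = roi_table["exclusion_reason"] != ""
        for _, row in roi_table[excluded].iterrows():
            logger.info(
                "roi %s/%s (%s): %s",
                row["image"], row["roi_id"], row["class"], row["exclusion_reason"],
            )

        stage = "aggregation"
        summary = summarize(roi_table)
        roi_table.to_csv(out_dir / "rois.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        (out_dir / "palette.json").write_text(
            json.dumps({str(k): v for k, v in CLASS_NAMES.items()})
        )
        cfg_dict = config.to_dict()
        manifest = {
            "config": cfg_dict,
            "config_hash": _config_hash(cfg_dict),
            "seed": config.seed,
            "software_version": __version__,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("run complete: %d ROIs, %d excluded", len(roi_table), int(excluded.sum()))
        return out_dir
    except Exception as err:
        (out_dir / "FAILED").write_text(f"stage={stage}\n{err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Repeat a run from its provenance manifest (identical tables)."""
    m = json.loads(Path(manifest_path).read_text())
    config = PipelineConfig.from_dict(m["config"])
    return run_pipeline(config, out_dir)
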