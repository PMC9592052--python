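"""Self-validation experiments on ground-truthed synthetic data.

These routines drive the whole pipeline against the scene generator and
report how well the decoration-ratio statistic and the segmentation
recover the known ground truth.  They back both the test suite and the
reproduction script.

Parameter-recovery runs use the generator's single-plane unblurred mode
with the default Poisson and read noise: that isolates the estimator
itself, whereas with PSF blur and purely geometric masks the statistic
carries a known toward-one bias (blur-dimmed rim pixels inside the
geometric cell boundary depress the cytoplasm reference) that
classifier-derived masks do not exhibit.  Segmentation quality is
assessed at the full default optics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .classes import CLASS_NAMES, OUTSIDE
from .quantify import quantify_image, summarize
from .scene import OpticsNoiseModel, SceneConfig, render_scene, sample_scene
from .segmentation import (
    detect_cells,
    merge_class_maps,
    refine_ring_fragments,
    train_two_channel_classifiers,
)
from .stack_io import project


def _seed(base: int, *branch: int) -> int:
    ss = np.random.SeedSequence([int(base), *map(int, branch)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def recovery_optics() -> OpticsNoiseModel:
    """Single-plane unblurred rendering with the default noise model."""
    return OpticsNoiseModel(n_zplanes=1, psf_sigma_xy=0.0, psf_sigma_z=0.0)


def default_2d_optics() -> OpticsNoiseModel:
    return OpticsNoiseModel(n_zplanes=1)


def _render_batch(config: SceneConfig, optics: OpticsNoiseModel, n_images: int, seed: int):
    scenes, projections, gts = [], [], []
    for i in range(n_images):
        scene = sample_scene(config, _seed(seed, i, 0))
        stack, gt = render_scene(scene, optics, seed=_seed(seed, i, 1))
        scenes.append(scene)
        projections.append(project(stack, "average"))
        gts.append(gt)
    return scenes, projections, gts


def decoration_recovery(
    decoration_ratio: dict[str, float],
    seed: int,
    n_images: int = 5,
    segmentation: str = "ground_truth",
    config: SceneConfig | None = None,
) -> pd.DataFrame:
    """Estimate per-class decoration ratios on generated cells.

    Returns a table with the estimated class means alongside the
    ground-truth class means recorded by the generator (undecorated
    patches count as ratio 0, so the patch truth sits below the nominal
    setting).
    """
    config = dataclasses.replace(
        config or SceneConfig(), decoration_ratio=dict(decoration_ratio)
    )
    optics = recovery_optics()
    scenes, projections, gts = _render_batch(config, optics, n_images, seed)

    if segmentation == "trained":
        # training fields deliberately include dividing cells so every
        # class has annotation examples (as an annotator would choose)
        train_config = dataclasses.replace(config, ring_fraction=0.5)
        _, train_projs, train_gts = _render_batch(
            train_config, optics, 2, _seed(seed, 999)
        )
        clf_factin, clf_tpm = train_two_channel_classifiers(
            [p.channel(0) for p in train_projs],
            [p.channel(1) for p in train_projs],
            [g.labels for g in train_gts],
            seed=_seed(seed, 998),
        )
        labels = [
            refine_ring_fragments(
                merge_class_maps(
                    clf_factin.predict(p.channel(0)), clf_tpm.predict(p.channel(1))
                )
            )
            for p in projections
        ]
    elif segmentation == "ground_truth":
        labels = gts
    else:
        raise ValueError(f"unknown segmentation mode {segmentation!r}")

    tables = []
    for proj, lab in zip(projections, labels):
        cells = detect_cells(lab)
        tables.append(quantify_image(proj, lab, cells))
    summary = summarize(pd.concat(tables, ignore_index=True))

    truth_acc: dict[str, list[float]] = {}
    for scene in scenes:
        for cls, val in scene.true_class_means().items():
            truth_acc.setdefault(cls, []).append(val)
    summary["truth"] = [
        float(np.mean(truth_acc.get(cls, [np.nan]))) for cls in summary["class"]
    ]
    summary["abs_error"] = (summary["mean"] - summary["truth"]).abs()
    summary["n_cells"] = sum(
        sum(not c.in_clump for c in scene.cells) for scene in scenes
    )
    return summary


def segmentation_quality(
    seed: int, n_train: int = 2, n_test: int = 2
) -> dict:
    """Train on synthetic images at the default optics and score
    held-out images: overall pixel accuracy and per-class IoU."""
    config = SceneConfig(ring_fraction=0.5)
    optics = default_2d_optics()
    _, train_projs, train_gts = _render_batch(config, optics, n_train, _seed(seed, 0))
    clf_factin, clf_tpm = train_two_channel_classifiers(
        [p.channel(0) for p in train_projs],
        [p.channel(1) for p in train_projs],
        [g.labels for g in train_gts],
        seed=_seed(seed, 1),
    )
    accs, inter, union = [], {}, {}
    _, test_projs, test_gts = _render_batch(config, optics, n_test, _seed(seed, 2))
    for proj, gt in zip(test_projs, test_gts):
        pred = refine_ring_fragments(
            merge_class_maps(
                clf_factin.predict(proj.channel(0)), clf_tpm.predict(proj.channel(1))
            )
        )
        accs.append(float((pred.labels == gt.labels).mean()))
        for code, name in CLASS_NAMES.items():
            a = pred.labels == code
            b = gt.labels == code
            if not b.any():
                continue
            inter[name] = inter.get(name, 0) + int((a & b).sum())
            union[name] = union.get(name, 0) + int((a | b).sum())
    iou = {name: inter[name] / union[name] for name in inter}
    return {
        "accuracy": float(np.mean(accs)),
        "iou": iou,
        "holdout_accuracy": (clf_factin.holdout_accuracy_, clf_tpm.holdout_accuracy_),
    }


def toy_cell():
    """Piecewise-constant two-channel cell with closed-form statistics.

    A 30x90 rectangular cell whose left 30x30 block is a patch ROI (one
    third of the cell area).  Channel values are chosen so the structure
    signal above cytoplasm is 90 (F-actin) and 40 (tropomyosin) and the
    whole-cell means above the zero outside background are 40 and 20,
    giving a decoration ratio of (40/90)*(40/20) = 8/9 exactly.

    Returns ``(projected, label_image, cell_instance)``.
    """
    from .classes import CYTOPLASM, PATCH, LabelImage
    from .segmentation import CellInstance
    from .stack_io import ProjectedImage

    h, w = 60, 120
    factin = np.zeros((h, w))
    tpm = np.zeros((h, w))
    labels = np.full((h, w), OUTSIDE, dtype=np.uint8)
    cell = np.zeros((h, w), dtype=bool)
    cell[10:40, 10:100] = True
    roi = np.zeros((h, w), dtype=bool)
    roi[10:40, 10:40] = True
    cyt = cell & ~roi
    factin[cyt] = 10.0
    factin[roi] = 100.0
    tpm[cyt] = 20.0 / 3.0
    tpm[roi] = 20.0 / 3.0 + 40.0
    labels[cyt] = CYTOPLASM
    labels[roi] = PATCH
    projected = ProjectedImage(
        data=np.stack([factin, tpm]),
        projection_mode="average",
        pixel_size_nm=69.0,
        channel_names=["factin", "tpm"],
    )
    instance = CellInstance(cell_id=0, mask=cell, area_px=int(cell.sum()))
    return projected, LabelImage(labels), instance


def clump_flag_sensitivity(seed: int, n_scenes: int = 12) -> float:
    """Fraction of deliberately generated clumps flagged by the default
    area rule.  One clump of 3-5 touching cells per scene."""
    config = SceneConfig(n_cells=5, n_clumps=1)
    optics = OpticsNoiseModel.noiseless_2d()
    hits = 0
    for i in range(n_scenes):
        scene = sample_scene(config, _seed(seed, i))
        _, gt = render_scene(scene, optics)
        cells = detect_cells(gt)
        hits += any(c.is_clump for c in cells)
    return hits / n_scenes
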