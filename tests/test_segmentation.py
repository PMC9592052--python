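import numpy as np
import pytest

from tpmquant import (
    CABLE,
    CYTOPLASM,
    OUTSIDE,
    PATCH,
    RING,
    LabelImage,
    OpticsNoiseModel,
    SceneConfig,
    TrainablePixelClassifier,
    detect_cells,
    merge_class_maps,
    render_scene,
    sample_scene,
    threshold_segment,
)
from tpmquant.classes import UNLABELLED
from tpmquant.segmentation import ThresholdParams, compute_features, subsample_annotations


# ---------------------------------------------------------------------------
# trainable classifier
# ---------------------------------------------------------------------------


def test_feature_bank_shape():
    img = np.random.default_rng(0).random((32, 32))
    feats = compute_features(img, scales=(1, 2, 4, 8))
    # raw + 3 per scale + DoG between consecutive scales
    assert feats.shape == (32, 32, 1 + 3 * 4 + 3)
    assert np.array_equal(feats[..., 0], img)


@pytest.fixture(scope="module")
def trained_factin(default2d_optics):
    """Classifier for the F-actin channel trained on two noisy images."""
    imgs, anns = [], []
    cfg = SceneConfig(field_size_px=(320, 320), n_cells=2, cell_length_range_um=(5, 8))
    for i in range(2):
        scene = sample_scene(cfg, seed=500 + i)
        stack, gt = render_scene(scene, default2d_optics)
        ann = subsample_annotations(gt.labels, 0.02, seed=i)
        ann[np.isin(ann, [CABLE, RING])] = CYTOPLASM
        imgs.append(stack.data[0, 0, 0])
        anns.append(ann)
    clf = TrainablePixelClassifier(
        class_set=("outside", "cytoplasm", "patch"), random_state=1
    )
    clf.fit(imgs, anns, pixel_size_nm=69.0)
    return clf, imgs, anns, cfg


def test_holdout_accuracy_and_probe(trained_factin, default2d_optics):
    clf, _, _, cfg = trained_factin
    assert clf.holdout_accuracy_ >= 0.95
    scene = sample_scene(cfg, seed=555)
    stack, gt = render_scene(scene, default2d_optics)
    pred = clf.predict(stack.data[0, 0, 0])
    # a pixel at the centre of a bright patch is labeled patch
    patch_px = gt.labels == PATCH
    assert (pred[patch_px] == PATCH).mean() > 0.5
    # same-distribution accuracy over the classifier's own classes
    eval_px = ~np.isin(gt.labels, [CABLE, RING])
    assert (pred[eval_px] == gt.labels[eval_px]).mean() >= 0.95


def test_blank_image_mostly_outside(trained_factin):
    clf = trained_factin[0]
    rng = np.random.default_rng(3)
    blank = rng.poisson(50.0, size=(160, 160)).astype(float)
    pred = clf.predict(blank)
    assert (pred == OUTSIDE).mean() >= 0.99


def test_training_determinism_and_order_invariance(trained_factin):
    clf, imgs, anns, _ = trained_factin
    probe = imgs[0]
    again = TrainablePixelClassifier(
        class_set=("outside", "cytoplasm", "patch"), random_state=1
    ).fit(imgs, anns)
    permuted = TrainablePixelClassifier(
        class_set=("outside", "cytoplasm", "patch"), random_state=1
    ).fit(imgs[::-1], anns[::-1])
    assert np.array_equal(clf.predict(probe), again.predict(probe))
    assert np.array_equal(clf.predict(probe), permuted.predict(probe))


def test_missing_class_labels_error():
    img = np.random.default_rng(0).random((64, 64))
    ann = np.full((64, 64), UNLABELLED, dtype=np.uint8)
    ann[:8] = CYTOPLASM
    ann[8:16] = PATCH
    with pytest.raises(ValueError, match="outside"):
        TrainablePixelClassifier(class_set=("outside", "cytoplasm", "patch")).fit(
            [img], [ann]
        )


def test_calibration_mismatch_error(trained_factin):
    clf = trained_factin[0]
    with pytest.raises(ValueError, match="pixel size"):
        clf.predict(np.zeros((32, 32)), pixel_size_nm=100.0)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def test_merge_precedence():
    factin = np.array([[PATCH, PATCH, CYTOPLASM, OUTSIDE]], dtype=np.uint8)
    tpm = np.array([[CABLE, RING, CABLE, OUTSIDE]], dtype=np.uint8)
    merged = merge_class_maps(factin, tpm)
    assert merged.labels.tolist() == [[PATCH, RING, CABLE, OUTSIDE]]
    assert merged.provenance["cable"] == "tpm"
    assert merged.provenance["patch"] == "factin"


def test_merge_identity_without_structures():
    factin = np.array([[CYTOPLASM, OUTSIDE]], dtype=np.uint8)
    tpm = np.array([[CYTOPLASM, OUTSIDE]], dtype=np.uint8)
    merged = merge_class_maps(factin, tpm)
    assert merged.labels.tolist() == [[CYTOPLASM, OUTSIDE]]


def test_merge_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        merge_class_maps(np.zeros((4, 4), np.uint8), np.zeros((4, 5), np.uint8))


# ---------------------------------------------------------------------------
# cell instances and clumps
# ---------------------------------------------------------------------------


def _labels_with_rectangles(rects, shape=(128, 128)):
    lab = np.full(shape, OUTSIDE, dtype=np.uint8)
    for (r0, r1, c0, c1) in rects:
        lab[r0:r1, c0:c1] = CYTOPLASM
    return LabelImage(lab)


def test_detect_cells_flags_large_clump():
    rects = [(r, r + 10, c, c + 20) for r in (5, 25, 45, 65) for c in (5, 40)]
    rects.append((90, 120, 40, 80))  # 1200 px "clump" vs 200 px cells
    cells = detect_cells(_labels_with_rectangles(rects), min_area=100)
    assert len(cells) == 9
    clumps = [c for c in cells if c.is_clump]
    assert len(clumps) == 1
    assert clumps[0].area_px == 1200


def test_single_cell_not_a_clump():
    cells = detect_cells(_labels_with_rectangles([(10, 30, 10, 60)]), min_area=100)
    assert len(cells) == 1 and not cells[0].is_clump


def test_touching_cells_form_one_instance():
    lab = np.full((64, 64), OUTSIDE, dtype=np.uint8)
    lab[10:20, 10:30] = CYTOPLASM
    lab[20:30, 30:50] = CYTOPLASM  # touches diagonally at (20, 30)
    cells = detect_cells(LabelImage(lab), min_area=50)
    assert len(cells) == 1


def test_instances_partition_foreground(exact_scene):
    _, _, gt = exact_scene
    cells = detect_cells(gt)
    union = np.zeros(gt.shape, dtype=int)
    for c in cells:
        union += c.mask
    assert union.max() <= 1  # disjoint
    assert np.array_equal(union.astype(bool), gt.labels != OUTSIDE)


def test_detect_cells_empty():
    assert detect_cells(_labels_with_rectangles([])) == []


# ---------------------------------------------------------------------------
# rule-based fallback
# ---------------------------------------------------------------------------


def test_threshold_segment_iou_noiseless():
    cfg = SceneConfig(field_size_px=(384, 384), n_cells=1, ring_fraction=1.0)
    scene = sample_scene(cfg, seed=11)
    optics = OpticsNoiseModel(n_zplanes=1, poisson_noise=False, read_noise_sd=0.0)
    stack, gt = render_scene(scene, optics)
    fmap = threshold_segment(
        stack.data[0, 0, 0], ThresholdParams(classes=("outside", "cytoplasm", "patch"))
    )
    tmap = threshold_segment(
        stack.data[0, 1, 0],
        ThresholdParams(classes=("outside", "cytoplasm", "cable", "ring")),
    )
    pred = merge_class_maps(fmap, tmap)
    for code in (OUTSIDE, CYTOPLASM, PATCH, CABLE, RING):
        truth = gt.labels == code
        if not truth.any():
            continue
        guess = pred.labels == code
        iou = (guess & truth).sum() / (guess | truth).sum()
        assert iou >= 0.6, f"class {code} IoU {iou:.2f}"


def test_threshold_segment_constant_image_all_outside():
    mask = threshold_segment(np.full((64, 64), 7.0), ThresholdParams())
    assert np.all(mask == OUTSIDE)


def test_threshold_segment_dim_patch_absent():
    img = np.full((96, 96), 50.0)
    img[20:80, 20:80] = 450.0  # a cell
    img[45:50, 45:50] = 520.0  # spot below the detection threshold
    mask = threshold_segment(img, ThresholdParams())
    assert not np.any(mask == PATCH)
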