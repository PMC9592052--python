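"""Supervised per-pixel structure classification and cell-instance detection.

The classifier mirrors the trainable-segmentation approach: each pixel
is described by a multiscale filter bank (raw intensity; Gaussian
smoothing, gradient magnitude and Laplacian at several scales;
difference-of-Gaussians between consecutive scales) and classified by a
random forest trained on sparse annotations.  Following the two-channel
protocol, patches plus background classes are detected on the F-actin
channel while cables and rings are detected on the tropomyosin channel;
the two maps are merged under a fixed precedence.

A deterministic rule-based fallback (:func:`threshold_segment`) is
provided for data without training annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor
from skimage.measure import regionprops
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .classes import (
    CABLE,
    CLASS_CODES,
    CLASS_NAMES,
    CYTOPLASM,
    OUTSIDE,
    PATCH,
    RING,
    UNLABELLED,
    LabelImage,
)

EIGHT_CONN = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# feature bank
# ---------------------------------------------------------------------------


def compute_features(image: np.ndarray, scales=(1, 2, 4, 8)) -> np.ndarray:
    """Multiscale per-pixel feature bank, shape (Y, X, F).

    Features: raw intensity; at each scale sigma the Gaussian-smoothed
    intensity, gradient magnitude and Laplacian; difference-of-Gaussians
    between consecutive scales.
    """
    image = np.asarray(image, dtype=float)
    feats = [image]
    smoothed = []
    for s in scales:
        g = ndimage.gaussian_filter(image, s)
        smoothed.append(g)
        feats.append(g)
        feats.append(ndimage.gaussian_gradient_magnitude(image, s))
        feats.append(ndimage.gaussian_laplace(image, s))
    for a, b in zip(smoothed[:-1], smoothed[1:]):
        feats.append(a - b)
    return np.stack(feats, axis=-1)


# ---------------------------------------------------------------------------
# trainable per-pixel classifier (sklearn estimator)
# ---------------------------------------------------------------------------


class TrainablePixelClassifier(BaseEstimator):
    """Random-forest pixel classifier over a multiscale feature bank.

    Parameters
    ----------
    class_set : tuple of str
        Classes the classifier predicts; a subset of
        {outside, cytoplasm, patch, cable, ring}.
    feature_scales : tuple of float
        Sigmas (px) of the filter bank.
    n_estimators : int
        Trees in the forest.
    max_samples_per_class : int
        Training pixels sampled per class (seeded, order-invariant).
    holdout_fraction : float
        Fraction of sampled pixels held out to report accuracy.
    random_state : int
        Seed controlling sampling and the forest.

    Attributes
    ----------
    model_ : fitted RandomForestClassifier
    classes_ : class codes the model predicts
    holdout_accuracy_ : pixel accuracy on the held-out split
    pixel_size_nm_ : calibration of the training images (if given)
    """

    def __init__(
        self,
        class_set=("outside", "cytoplasm", "patch"),
        feature_scales=(1, 2, 4, 8),
        n_estimators=100,
        max_samples_per_class=4000,
        holdout_fraction=0.2,
        random_state=0,
    ):
        self.class_set = class_set
        self.feature_scales = feature_scales
        self.n_estimators = n_estimators
        self.max_samples_per_class = max_samples_per_class
        self.holdout_fraction = holdout_fraction
        self.random_state = random_state

    def fit(self, images, sparse_labels, pixel_size_nm: float | None = None):
        """Fit on sparsely annotated images.

        ``images`` is a list of 2D rasters; ``sparse_labels`` a matching
        list of uint8 maps where annotated pixels carry a class code and
        everything else is ``UNLABELLED`` (255).  Each class in
        ``class_set`` needs at least 50 annotated pixels.
        """
        if not self.class_set:
            raise ValueError("class_set must be nonempty")
        codes = [CLASS_CODES[name] for name in self.class_set]
        rows, labs = [], []
        for img, lab in zip(images, sparse_labels, strict=True):
            lab = np.asarray(lab)
            if lab.shape != np.asarray(img).shape:
                raise ValueError("label map shape does not match image")
            sel = np.isin(lab, codes)
            if not sel.any():
                continue
            feats = compute_features(img, self.feature_scales)
            rows.append(feats[sel])
            labs.append(lab[sel])
        X = np.concatenate(rows, axis=0) if rows else np.empty((0, 1))
        y = np.concatenate(labs, axis=0) if labs else np.empty((0,), dtype=np.uint8)

        counts = {name: int(np.sum(y == CLASS_CODES[name])) for name in self.class_set}
        missing = [name for name, c in counts.items() if c < 50]
        if missing:
            raise ValueError(
                f"insufficient annotations (<50 pixels) for classes: {missing}"
            )

        # canonical row order (lexicographic on features) makes the fit
        # invariant to the order in which training images are supplied
        order = np.lexsort(X.T)
        X, y = X[order], y[order]
        rng = np.random.default_rng(self.random_state)
        keep_parts = []
        for code in codes:
            idx = np.flatnonzero(y == code)
            if idx.size > self.max_samples_per_class:
                idx = rng.choice(idx, self.max_samples_per_class, replace=False)
            keep_parts.append(np.sort(idx))
        keep = np.concatenate(keep_parts)
        X, y = X[keep], y[keep]

        n_hold = max(int(round(self.holdout_fraction * len(y))), 1)
        perm = np.random.default_rng(self.random_state + 1).permutation(len(y))
        hold, train = perm[:n_hold], perm[n_hold:]
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.model_.fit(X[train], y[train])
        self.holdout_accuracy_ = float(
            np.mean(self.model_.predict(X[hold]) == y[hold])
        )
        self.classes_ = self.model_.classes_
        self.pixel_size_nm_ = pixel_size_nm
        return self

    def predict(self, image, pixel_size_nm: float | None = None) -> np.ndarray:
        """Argmax-posterior class code per pixel."""
        if not hasattr(self, "model_"):
            raise ValueError("classifier is not fitted")
        if (
            pixel_size_nm is not None
            and self.pixel_size_nm_ is not None
            and abs(pixel_size_nm - self.pixel_size_nm_) > 0.1 * self.pixel_size_nm_
        ):
            raise ValueError(
                f"pixel size {pixel_size_nm} nm differs from training calibration "
                f"{self.pixel_size_nm_} nm by more than 10%"
            )
        image = np.asarray(image, dtype=float)
        feats = compute_features(image, self.feature_scales)
        pred = self.model_.predict(feats.reshape(-1, feats.shape[-1]))
        return pred.reshape(image.shape).astype(np.uint8)


def train_classifier(images, sparse_labels, class_set, seed=0, **kwargs):
    """Functional wrapper: fit a :class:`TrainablePixelClassifier`."""
    clf = TrainablePixelClassifier(class_set=tuple(class_set), random_state=seed, **kwargs)
    return clf.fit(images, sparse_labels)


def classify_pixels(classifier, image, pixel_size_nm=None) -> np.ndarray:
    """Functional wrapper over :meth:`TrainablePixelClassifier.predict`."""
    return classifier.predict(image, pixel_size_nm=pixel_size_nm)


def subsample_annotations(
    label_image: np.ndarray, fraction: float, seed: int, min_per_class: int = 200
) -> np.ndarray:
    """Sparse class-balanced annotations from dense ground truth.

    Keeps a random ``fraction`` of each class's pixels but at least
    ``min_per_class`` (or all, for rarer classes) — emulating an
    annotator who deliberately labels examples of every class.  Stands
    in for interactive annotation when training on synthetic data.
    """
    rng = np.random.default_rng(seed)
    out = np.full_like(label_image, UNLABELLED)
    for code in np.unique(label_image):
        idx = np.flatnonzero(label_image.ravel() == code)
        n = min(max(int(round(fraction * idx.size)), min_per_class), idx.size)
        chosen = rng.choice(idx, n, replace=False)
        out.ravel()[chosen] = code
    return out


def train_two_channel_classifiers(
    factin_images,
    tpm_images,
    dense_labels,
    seed: int = 0,
    annotation_fraction: float = 0.02,
):
    """Fit the two-channel classifier pair from dense ground truth.

    Sparse class-balanced annotations are subsampled per image; each
    channel's classifier treats the other channel's structure classes
    as cytoplasm, so their bright pixels are learned as background with
    a different shape signature instead of being left unexplained.
    Returns ``(factin_classifier, tpm_classifier)``.
    """
    factin_anns, tpm_anns = [], []
    for i, lab in enumerate(dense_labels):
        ann = subsample_annotations(lab, annotation_fraction, seed=seed + i)
        fa = ann.copy()
        fa[np.isin(fa, [CABLE, RING])] = CYTOPLASM
        factin_anns.append(fa)
        ta = ann.copy()
        ta[ta == PATCH] = CYTOPLASM
        tpm_anns.append(ta)
    clf_factin = TrainablePixelClassifier(
        class_set=("outside", "cytoplasm", "patch"), random_state=seed
    ).fit(factin_images, factin_anns)
    clf_tpm = TrainablePixelClassifier(
        class_set=("outside", "cytoplasm", "cable", "ring"), random_state=seed
    ).fit(tpm_images, tpm_anns)
    return clf_factin, clf_tpm


# ---------------------------------------------------------------------------
# merging the two channel-wise class maps
# ---------------------------------------------------------------------------


def merge_class_maps(factin_map: np.ndarray, tpm_map: np.ndarray) -> LabelImage:
    """Combine per-channel masks into one label per pixel.

    Patches (and the cytoplasm/outside background) come from the
    F-actin channel; cables and rings from the tropomyosin channel.
    Overlaps resolve under the fixed precedence
    ring > patch > cable > cytoplasm > outside.
    """
    factin_map = np.asarray(factin_map)
    tpm_map = np.asarray(tpm_map)
    if factin_map.shape != tpm_map.shape:
        raise ValueError(
            f"shape mismatch: {factin_map.shape} vs {tpm_map.shape}"
        )
    out = np.full(factin_map.shape, OUTSIDE, dtype=np.uint8)
    out[(factin_map == CYTOPLASM) | (tpm_map == CYTOPLASM)] = CYTOPLASM
    out[tpm_map == CABLE] = CABLE
    out[factin_map == PATCH] = PATCH
    out[tpm_map == RING] = RING
    return LabelImage(
        out, provenance={"patch": "factin", "cable": "tpm", "ring": "tpm"}
    )


def refine_ring_fragments(
    label_image: LabelImage, min_ring_area_px: int = 50
) -> LabelImage:
    """Reassign implausibly small ring components to the cable class.

    A cytokinetic ring spans the cell diameter (~3.5 µm, ~50 px at
    69 nm/px) times its band thickness, so a connected ring component
    far below that area cannot be a ring; with an isotropic feature
    bank such fragments are almost always bright cable segments
    misclassified as ring.
    """
    labels = label_image.labels.copy()
    ring = labels == RING
    lab, n = ndimage.label(ring, structure=EIGHT_CONN)
    for comp in range(1, n + 1):
        m = lab == comp
        if int(m.sum()) < min_ring_area_px:
            labels[m] = CABLE
    return LabelImage(labels, provenance=dict(label_image.provenance))


# ---------------------------------------------------------------------------
# cell instances and clump flagging
# ---------------------------------------------------------------------------


@dataclass
class CellInstance:
    cell_id: int
    mask: np.ndarray
    area_px: int
    is_clump: bool = False


def detect_cells(
    label_image: LabelImage,
    min_area: int = 500,
    clump_area_factor: float = 2.5,
) -> list[CellInstance]:
    """Connected components of non-outside pixels, with clump flags.

    8-connected components smaller than ``min_area`` px² are dropped;
    components larger than ``clump_area_factor`` times the median
    component area are flagged ``is_clump`` (retained in the output but
    excluded from quantification).  A touching mother-daughter pair is
    by construction a single instance.
    """
    fg = label_image.labels != OUTSIDE
    lab, n = ndimage.label(fg, structure=EIGHT_CONN)
    if n == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    if keep.size == 0:
        return []
    median_area = float(np.median(areas[keep - 1]))
    out = []
    for cid, comp in enumerate(keep):
        area = int(areas[comp - 1])
        out.append(
            CellInstance(
                cell_id=cid,
                mask=lab == comp,
                area_px=area,
                is_clump=area > clump_area_factor * median_area,
            )
        )
    return out


# ---------------------------------------------------------------------------
# rule-based fallback segmentation
# ---------------------------------------------------------------------------


@dataclass
class ThresholdParams:
    """Rules for the deterministic fallback segmenter."""

    classes: tuple[str, ...] = ("outside", "cytoplasm", "patch")
    cell_sigma: float = 2.0  # px, smoothing before the cell threshold
    spot_min_excess: float = 280.0  # counts above the cytoplasm median;
    # above cable amplitudes so spot candidates do not fuse with cables
    spot_halfmax: float = 0.5  # per-component relative threshold
    max_patch_area: int = 250  # px^2; larger blobs are not patches
    max_patch_elongation: float = 3.0
    ridge_min_excess: float = 70.0  # counts above the cytoplasm median
    tensor_sigma: float = 2.0  # px, structure-tensor scale
    ring_angle_deg: float = 50.0  # pixels steeper than this vs the cell
    # long axis count as ring, shallower as cable
    palette: dict = field(default_factory=dict)


def _cell_mask_by_threshold(image: np.ndarray, sigma: float) -> np.ndarray:
    sm = ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma)
    med = np.median(sm)
    mad = np.median(np.abs(sm - med))
    thr = med + max(6.0 * mad, 0.02 * (sm.max() - med))
    mask = sm > thr
    mask = ndimage.binary_closing(mask, structure=EIGHT_CONN, iterations=2)
    return ndimage.binary_fill_holes(mask)


def _component_orientation(mask: np.ndarray) -> float:
    """Principal-axis angle of a pixel mask, in [0, pi)."""
    ys, xs = np.nonzero(mask)
    yc, xc = ys.mean(), xs.mean()
    cov = np.cov(np.stack([xs - xc, ys - yc]).astype(float)) + 1e-9 * np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, np.argmax(evals)]
    return float(np.arctan2(vy, vx) % np.pi)


def threshold_segment(image: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Deterministic rule-based class mask for one channel.

    Outside is split from cells by a robust global threshold; patches
    are compact bright spots found by background-subtracted per-blob
    half-max thresholding; cables and rings are ridge-enhanced line
    structures, disambiguated by their angle to the parent cell's long
    axis (rings run across the rod, cables along it).
    """
    image = np.asarray(image, dtype=float)
    out = np.full(image.shape, OUTSIDE, dtype=np.uint8)
    cells = _cell_mask_by_threshold(image, params.cell_sigma)
    if not cells.any():
        return out
    out[cells] = CYTOPLASM
    cyt_level = float(np.median(image[cells]))
    excess = np.where(cells, image - cyt_level, 0.0)

    if "patch" in params.classes:
        cand = excess > params.spot_min_excess
        lab, _ = ndimage.label(cand, structure=EIGHT_CONN)
        for prop in regionprops(lab, intensity_image=excess):
            if prop.area > params.max_patch_area:
                continue
            minor = max(prop.axis_minor_length, 1.0)
            if prop.axis_major_length / minor > params.max_patch_elongation:
                continue
            comp = lab == prop.label
            spot = comp & (excess >= params.spot_halfmax * prop.intensity_max)
            out[spot] = PATCH

    if "cable" in params.classes or "ring" in params.classes:
        cand = (excess > params.ridge_min_excess) & cells
        lab, _ = ndimage.label(cand, structure=EIGHT_CONN)
        cell_lab, _ = ndimage.label(cells, structure=EIGHT_CONN)
        # per-pixel orientation of the intensity landscape: a line
        # structure's dominant eigenvector is perpendicular to the line
        axx, axy, ayy = structure_tensor(
            ndimage.gaussian_filter(image, 1.0),
            sigma=params.tensor_sigma,
            order="xy",
        )
        line_angle = (0.5 * np.arctan2(2 * axy, axx - ayy) + np.pi / 2) % np.pi
        cell_angles: dict[int, float] = {}
        for prop in regionprops(lab):
            comp = lab == prop.label
            if prop.area < 6:
                continue
            minor = max(prop.axis_minor_length, 1.0)
            compact = (
                prop.area <= params.max_patch_area
                and prop.axis_major_length / minor < 2.0
            )
            if compact:
                continue  # bright spot on this channel, not a line structure
            host = int(np.bincount(cell_lab[comp]).argmax())
            if host not in cell_angles:
                cell_angles[host] = _component_orientation(cell_lab == host)
            delta = np.abs(line_angle[comp] - cell_angles[host])
            delta = np.minimum(delta, np.pi - delta)
            is_ring = np.degrees(delta) > params.ring_angle_deg
            yy, xx = np.nonzero(comp)
            if "cable" in params.classes:
                sel = ~is_ring if "ring" in params.classes else np.ones_like(yy, bool)
                out[yy[sel], xx[sel]] = CABLE
            if "ring" in params.classes and is_ring.any():
                # trim the blurred skirt: keep ring pixels above half of
                # the ring's own peak excess
                vals = excess[yy[is_ring], xx[is_ring]]
                keep = vals >= params.spot_halfmax * vals.max()
                out[yy[is_ring][keep], xx[is_ring][keep]] = RING
    return out
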