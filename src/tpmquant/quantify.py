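"""Per-structure decoration-ratio quantification.

For every structure ROI the statistic is

    r = (roi_tpm - cyt_tpm) / (roi_factin - cyt_factin)
        x (cell_factin - out_factin) / (cell_tpm - out_tpm)

i.e. the tropomyosin/F-actin intensity ratio on the structure above the
parent cell's cytoplasm levels, normalised by the two channels'
whole-cell expression levels above the extracellular background.  A
fully decorated structure therefore scores ~1 regardless of relative
expression or acquisition gain, and an undecorated one scores ~0.

Robustness choices: cable ROIs are eroded by one pixel to avoid
cytoplasm bleed-in; the darkest 10% of structure pixels and brightest
10% of cytoplasm pixels are trimmed before averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import CLASS_NAMES, CYTOPLASM, OUTSIDE, STRUCTURE_CLASSES, LabelImage
from .segmentation import EIGHT_CONN, CellInstance
from .stack_io import ProjectedImage

CHANNEL_ROLES = ("factin", "tpm")


class ExcludedROIError(ValueError):
    """Raised when an ROI fails the reference-signal preconditions."""


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def trimmed_mean(values, fraction: float, side: str) -> float:
    """Mean after discarding floor(fraction*n) values from one extreme.

    ``side='lowest'`` drops the darkest values, ``side='highest'`` the
    brightest; ties are broken by a stable sort, so exactly
    floor(fraction*n) values are dropped.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("trimmed_mean of an empty list")
    if not 0.0 <= fraction < 0.5:
        raise ValueError(f"trim fraction must be in [0, 0.5), got {fraction}")
    if side not in ("lowest", "highest"):
        raise ValueError(f"side must be 'lowest' or 'highest', got {side!r}")
    k = math.floor(fraction * values.size)
    if k == 0:
        return float(values.mean())
    order = np.sort(values, kind="stable")
    kept = order[k:] if side == "lowest" else order[: values.size - k]
    return float(kept.mean())


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------


@dataclass
class StructureROI:
    roi_id: int
    class_name: str  # patch | cable | ring
    cell_id: int
    mask: np.ndarray  # full-frame boolean pixel set
    measured_mask: np.ndarray  # eroded for cables, == mask otherwise
    erosion_fallback: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def extract_rois(
    label_image: LabelImage,
    cells: list[CellInstance],
    erode_cables: bool = True,
    min_structure_area_px: int = 5,
) -> list[StructureROI]:
    """One ROI per connected structure component per non-clump cell.

    Cable ROIs get a measured set eroded by one pixel (3x3 square
    element) to strictly separate cable from cytoplasm signal; if
    erosion empties a cable the original set is retained and flagged.
    Components below ``min_structure_area_px`` are discarded: a real
    fluorescent structure cannot image smaller than the PSF core, so
    such specks are segmentation noise.
    """
    rois: list[StructureROI] = []
    rid = 0
    for cell in cells:
        if cell.is_clump:
            continue
        for code in STRUCTURE_CLASSES:
            cls = CLASS_NAMES[code]
            mask = (label_image.labels == code) & cell.mask
            if not mask.any():
                continue
            lab, n = ndimage.label(mask, structure=EIGHT_CONN)
            for comp in range(1, n + 1):
                m = lab == comp
                if int(m.sum()) < min_structure_area_px:
                    continue
                fallback = False
                measured = m
                if cls == "cable" and erode_cables:
                    eroded = ndimage.binary_erosion(m, structure=EIGHT_CONN)
                    if eroded.any():
                        measured = eroded
                    else:
                        fallback = True
                rois.append(
                    StructureROI(
                        roi_id=rid,
                        class_name=cls,
                        cell_id=cell.cell_id,
                        mask=m,
                        measured_mask=measured,
                        erosion_fallback=fallback,
                    )
                )
                rid += 1
    return rois


# ---------------------------------------------------------------------------
# intensity measurement
# ---------------------------------------------------------------------------


@dataclass
class ChannelMeasurements:
    """Trimmed/plain means feeding the decoration ratio, per channel role."""

    roi_mean: dict[str, float]  # trimmed mean over the measured set
    cyt: dict[str, float]  # trimmed mean over the cell's cytoplasm
    cell: dict[str, float]  # untrimmed mean over the whole cell
    out: dict[str, float]  # untrimmed mean over outside pixels
    area_px: int
    area_um2: float
    trim_fraction: float


def measure_roi(
    roi: StructureROI,
    projected: ProjectedImage,
    cell: CellInstance,
    label_image: LabelImage,
    channel_roles: dict[str, int] | None = None,
    trim_fraction: float = 0.10,
    valid_mask: np.ndarray | None = None,
) -> ChannelMeasurements:
    """Measure one ROI on the average z-projection of both channels.

    The darkest ``trim_fraction`` of structure pixels and the brightest
    ``trim_fraction`` of the parent cell's cytoplasm pixels are omitted;
    whole-cell and outside-background means are untrimmed.  Pixels
    masked out by registration (``valid_mask`` False) are excluded from
    every statistic.
    """
    roles = channel_roles or {"factin": 0, "tpm": 1}
    valid = (
        np.ones(label_image.shape, dtype=bool) if valid_mask is None else valid_mask
    )
    cyt_mask = label_image.mask(CYTOPLASM) & cell.mask & valid
    if not cyt_mask.any():
        raise ExcludedROIError(
            f"cell {cell.cell_id} has no cytoplasm pixels to reference against"
        )
    out_mask = label_image.mask(OUTSIDE) & valid
    meas_mask = roi.measured_mask & valid
    if not meas_mask.any():
        raise ExcludedROIError(f"roi {roi.roi_id}: no valid measured pixels")

    roi_mean, cyt, cell_m, out = {}, {}, {}, {}
    for role in CHANNEL_ROLES:
        img = projected.channel(roles[role])
        roi_mean[role] = trimmed_mean(img[meas_mask], trim_fraction, "lowest")
        cyt[role] = trimmed_mean(img[cyt_mask], trim_fraction, "highest")
        cell_m[role] = float(img[cell.mask & valid].mean())
        out[role] = float(img[out_mask].mean()) if out_mask.any() else 0.0
        if cell_m[role] < out[role]:
            import warnings

            warnings.warn(
                f"cell {cell.cell_id}: mean {role} signal below outside background",
                RuntimeWarning,
                stacklevel=2,
            )
    px_um = projected.pixel_size_nm / 1000.0
    return ChannelMeasurements(
        roi_mean=roi_mean,
        cyt=cyt,
        cell=cell_m,
        out=out,
        area_px=roi.area_px,
        area_um2=roi.area_px * px_um**2,
        trim_fraction=trim_fraction,
    )


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------


def decoration_ratio(m: ChannelMeasurements, eps: float | None = None) -> float:
    """Normalised tropomyosin decoration ratio of one ROI.

    Raises :class:`ExcludedROIError` when the F-actin structure signal
    above cytoplasm, or the whole-cell tropomyosin signal above outside
    background, is not positive — such ROIs carry no reference signal
    and are reported as excluded rather than silently zeroed.
    """
    if eps is None:
        eps = 1e-6 * max(m.out["factin"], m.out["tpm"], 1.0)
    num_tpm = m.roi_mean["tpm"] - m.cyt["tpm"]
    num_factin = m.roi_mean["factin"] - m.cyt["factin"]
    norm_factin = m.cell["factin"] - m.out["factin"]
    norm_tpm = m.cell["tpm"] - m.out["tpm"]
    if num_factin <= eps:
        raise ExcludedROIError("excluded: non-positive reference signal (structure F-actin)")
    if norm_tpm <= eps:
        raise ExcludedROIError("excluded: non-positive reference signal (cell tropomyosin)")
    return (num_tpm / num_factin) * (norm_factin / norm_tpm)


def aggregate(ratios: list[tuple[str, float]]) -> pd.DataFrame:
    """Per-class n, mean and s.e.m. (sample sd over sqrt(n)).

    With n = 1 the s.e.m. is undefined and reported as NaN, never 0.
    """
    df = pd.DataFrame(ratios, columns=["class", "r"])
    rows = []
    for cls, grp in df.groupby("class", sort=True):
        n = len(grp)
        sem = float(grp["r"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"class": cls, "n": n, "mean": float(grp["r"].mean()), "sem": sem})
    return pd.DataFrame(rows, columns=["class", "n", "mean", "sem"])


# ---------------------------------------------------------------------------
# image-level driver
# ---------------------------------------------------------------------------


def quantify_image(
    projected: ProjectedImage,
    label_image: LabelImage,
    cells: list[CellInstance],
    channel_roles: dict[str, int] | None = None,
    trim_fraction: float = 0.10,
    erode_cables: bool = True,
    min_structure_area_px: int = 5,
    valid_mask: np.ndarray | None = None,
    image_name: str = "",
) -> pd.DataFrame:
    """Quantify every structure ROI of one image into a tidy table.

    Excluded ROIs stay in the table with their reason; their ``r`` is
    NaN and they are skipped by :func:`aggregate`.
    """
    rois = extract_rois(
        label_image,
        cells,
        erode_cables=erode_cables,
        min_structure_area_px=min_structure_area_px,
    )
    cell_by_id = {c.cell_id: c for c in cells}
    records = []
    for roi in rois:
        rec = {
            "image": image_name,
            "cell_id": roi.cell_id,
            "roi_id": roi.roi_id,
            "class": roi.class_name,
            "area_px": roi.area_px,
            "erosion_fallback": roi.erosion_fallback,
            "exclusion_reason": "",
            "r": float("nan"),
        }
        try:
            m = measure_roi(
                roi,
                projected,
                cell_by_id[roi.cell_id],
                label_image,
                channel_roles=channel_roles,
                trim_fraction=trim_fraction,
                valid_mask=valid_mask,
            )
            rec.update(
                area_um2=m.area_um2,
                roi_mean_factin=m.roi_mean["factin"],
                roi_mean_tpm=m.roi_mean["tpm"],
                cyt_factin=m.cyt["factin"],
                cyt_tpm=m.cyt["tpm"],
                cell_factin=m.cell["factin"],
                cell_tpm=m.cell["tpm"],
                out_factin=m.out["factin"],
                out_tpm=m.out["tpm"],
            )
            rec["r"] = decoration_ratio(m)
        except ExcludedROIError as err:
            rec["exclusion_reason"] = str(err)
        records.append(rec)
    columns = [
        "image", "cell_id", "roi_id", "class", "area_px", "area_um2",
        "roi_mean_factin", "roi_mean_tpm", "cyt_factin", "cyt_tpm",
        "cell_factin", "cell_tpm", "out_factin", "out_tpm",
        "erosion_fallback", "r", "exclusion_reason",
    ]
    return pd.DataFrame(records, columns=columns)


def summarize(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-ROI table (possibly over many images) per class."""
    ok = roi_table[roi_table["exclusion_reason"] == ""]
    return aggregate(list(zip(ok["class"], ok["r"])))
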