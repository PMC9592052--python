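import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpmquant import (
    CABLE,
    CYTOPLASM,
    OUTSIDE,
    PATCH,
    ExcludedROIError,
    LabelImage,
    aggregate,
    decoration_ratio,
    detect_cells,
    extract_rois,
    measure_roi,
    quantify_image,
    summarize,
    trimmed_mean,
)
from tpmquant.segmentation import CellInstance

from conftest import make_toy_cell


# ---------------------------------------------------------------------------
# trimmed mean
# ---------------------------------------------------------------------------


def oracle_trimmed_mean(values, fraction, side):
    """Independent sort-discard-average reference."""
    values = sorted(values)
    k = math.floor(fraction * len(values))
    kept = values[k:] if side == "lowest" else values[: len(values) - k]
    return sum(kept) / len(kept)


def test_trimmed_mean_worked_example():
    assert trimmed_mean(range(1, 11), 0.10, "lowest") == pytest.approx(6.0)


def test_trimmed_mean_trivial_cases():
    assert trimmed_mean([4.2] * 17, 0.3, "highest") == pytest.approx(4.2)
    vals = [3.0, 1.0, 7.0]
    assert trimmed_mean(vals, 0.0, "lowest") == pytest.approx(np.mean(vals))
    with pytest.raises(ValueError):
        trimmed_mean([], 0.1, "lowest")
    with pytest.raises(ValueError):
        trimmed_mean([1.0], 0.6, "lowest")
    with pytest.raises(ValueError):
        trimmed_mean([1.0], 0.1, "middle")


@settings(max_examples=200, derandomize=True)
@given(
    values=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
    fraction=st.floats(0.0, 0.49),
    side=st.sampled_from(["lowest", "highest"]),
)
def test_trimmed_mean_matches_oracle(values, fraction, side):
    assert trimmed_mean(values, fraction, side) == pytest.approx(
        oracle_trimmed_mean(values, fraction, side), rel=1e-9, abs=1e-9
    )


# ---------------------------------------------------------------------------
# ROI extraction and erosion
# ---------------------------------------------------------------------------


def _single_cell_setup(structure_mask, code=CABLE):
    lab = np.full(structure_mask.shape, CYTOPLASM, dtype=np.uint8)
    lab[0, :] = OUTSIDE
    lab[structure_mask] = code
    cell_mask = lab != OUTSIDE
    cells = [CellInstance(cell_id=0, mask=cell_mask, area_px=int(cell_mask.sum()))]
    return LabelImage(lab), cells


def test_cable_erosion_keeps_centre():
    m = np.zeros((12, 12), dtype=bool)
    m[5:8, 5:8] = True  # 3x3 square
    lab, cells = _single_cell_setup(m)
    (roi,) = extract_rois(lab, cells)
    assert roi.class_name == "cable"
    assert roi.measured_mask.sum() == 1
    assert roi.measured_mask[6, 6]
    assert not roi.erosion_fallback


def test_thin_cable_erosion_fallback():
    m = np.zeros((12, 12), dtype=bool)
    m[6, 2:10] = True  # 1 px wide line
    lab, cells = _single_cell_setup(m)
    (roi,) = extract_rois(lab, cells)
    assert roi.erosion_fallback
    assert np.array_equal(roi.measured_mask, roi.mask)


def test_patch_not_eroded():
    m = np.zeros((12, 12), dtype=bool)
    m[5:8, 5:8] = True
    lab, cells = _single_cell_setup(m, code=PATCH)
    (roi,) = extract_rois(lab, cells)
    assert np.array_equal(roi.measured_mask, roi.mask)


def test_clump_cells_yield_no_rois():
    m = np.zeros((12, 12), dtype=bool)
    m[5:8, 5:8] = True
    lab, cells = _single_cell_setup(m)
    cells[0].is_clump = True
    assert extract_rois(lab, cells) == []


def oracle_erode(mask):
    """Brute-force 3x3 neighbourhood check."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < h and 0 <= jj < w and mask[ii, jj]):
                        ok = False
            out[i, j] = ok
    return out


def test_erosion_matches_bruteforce_oracle():
    from scipy.ndimage import binary_erosion

    rng = np.random.default_rng(12)
    for _ in range(25):
        mask = rng.random((16, 16)) < 0.6
        assert np.array_equal(
            binary_erosion(mask, structure=np.ones((3, 3), bool)), oracle_erode(mask)
        )


# ---------------------------------------------------------------------------
# measurement and the decoration ratio
# ---------------------------------------------------------------------------


def test_piecewise_constant_measurement_exact():
    projected, lab, cell = make_toy_cell()
    (roi,) = extract_rois(lab, [cell])
    m = measure_roi(roi, projected, cell, lab)
    assert m.roi_mean["factin"] == pytest.approx(100.0)
    assert m.cyt["factin"] == pytest.approx(10.0)
    assert m.out["factin"] == pytest.approx(0.0)
    assert m.cell["factin"] == pytest.approx(40.0)  # 1/3 at 100, 2/3 at 10
    assert m.roi_mean["tpm"] == pytest.approx(20.0 / 3.0 + 40.0)
    assert m.cell["tpm"] == pytest.approx(20.0)


def test_worked_example_ratio():
    """num_tpm=40, num_factin=90, norm_factin=40, norm_tpm=20 -> 8/9."""
    projected, lab, cell = make_toy_cell()
    (roi,) = extract_rois(lab, [cell])
    m = measure_roi(roi, projected, cell, lab)
    assert decoration_ratio(m) == pytest.approx(8.0 / 9.0, abs=1e-12)


def test_proportional_channels_give_unit_ratio():
    projected, lab, cell = make_toy_cell()
    for k in (0.5, 1.0, 3.0):
        projected.data[1] = k * projected.data[0]
        (roi,) = extract_rois(lab, [cell])
        m = measure_roi(roi, projected, cell, lab)
        assert decoration_ratio(m) == pytest.approx(1.0, abs=1e-9)


def test_nonpositive_reference_excluded():
    projected, lab, cell = make_toy_cell()
    projected.data[0] = np.where(projected.data[0] > 0, 10.0, 0.0)  # flat cell
    (roi,) = extract_rois(lab, [cell])
    m = measure_roi(roi, projected, cell, lab)
    with pytest.raises(ExcludedROIError, match="non-positive reference"):
        decoration_ratio(m)


def test_missing_cytoplasm_errors():
    projected, lab, cell = make_toy_cell()
    labels = lab.labels.copy()
    labels[labels == CYTOPLASM] = PATCH
    lab2 = LabelImage(labels)
    (roi, *_) = extract_rois(lab2, [cell])
    with pytest.raises(ExcludedROIError, match="cytoplasm"):
        measure_roi(roi, projected, cell, lab2)


def test_ground_truth_ratio_recovery_noiseless(exact_scene, exact_projection):
    """Unblurred, noiseless synthetic cells: every ROI's above-cytoplasm
    channel ratio reproduces the generator setting to 1e-6."""
    scene, _, gt = exact_scene
    cells = detect_cells(gt)
    table = quantify_image(exact_projection, gt, cells)
    ok = table[table["exclusion_reason"] == ""]
    for _, row in ok.iterrows():
        first_factor = (row["roi_mean_tpm"] - row["cyt_tpm"]) / (
            row["roi_mean_factin"] - row["cyt_factin"]
        )
        if row["class"] == "patch":
            assert (
                abs(first_factor - scene.decoration_ratio["patch"]) < 1e-6
                or abs(first_factor) < 1e-6  # undecorated patch
                or 0 < first_factor < scene.decoration_ratio["patch"]  # merged pair
            )
        else:
            assert first_factor == pytest.approx(
                scene.decoration_ratio[row["class"]], abs=1e-6
            )


def test_scale_invariance_whole_channel(exact_scene, exact_projection):
    import dataclasses

    scene, _, gt = exact_scene
    cells = detect_cells(gt)
    base = quantify_image(exact_projection, gt, cells)
    data = exact_projection.data.copy()
    data[1] *= 5.0
    after = quantify_image(
        dataclasses.replace(exact_projection, data=data), gt, cells
    )
    ok = base["exclusion_reason"] == ""
    assert np.allclose(base.loc[ok, "r"], after.loc[ok, "r"], atol=1e-9)


def test_background_offset_invariance(exact_scene, exact_projection):
    """Adding a constant offset to a channel shifts roi/cyt/cell/out
    together and leaves every ratio unchanged."""
    import dataclasses

    _, _, gt = exact_scene
    cells = detect_cells(gt)
    base = quantify_image(exact_projection, gt, cells)
    data = exact_projection.data.copy()
    data[1] += 123.0
    after = quantify_image(
        dataclasses.replace(exact_projection, data=data), gt, cells
    )
    ok = base["exclusion_reason"] == ""
    assert np.allclose(base.loc[ok, "r"], after.loc[ok, "r"], atol=1e-9)


def test_monotonicity_in_channel2_amplitude(fast_config, default2d_optics):
    """Raising the tropomyosin structure amplitude never lowers the
    estimated class means."""
    from tpmquant import project, render_scene, sample_scene
    from tpmquant.scene import SceneConfig
    import dataclasses

    means = []
    for r in (0.3, 0.6, 0.9):
        cfg = dataclasses.replace(
            fast_config,
            decoration_ratio={"patch": r, "cable": r, "ring": r},
            decorated_patch_fraction=1.0,
        )
        scene = sample_scene(cfg, seed=77)
        stack, gt = render_scene(scene, default2d_optics, seed=101)
        table = quantify_image(project(stack, "average"), gt, detect_cells(gt))
        summary = summarize(table).set_index("class")["mean"]
        means.append(summary)
    for cls in means[0].index:
        series = [m[cls] for m in means if cls in m.index]
        assert all(a <= b for a, b in zip(series, series[1:]))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_aggregate_worked_example():
    out = aggregate([("cable", 0.9), ("cable", 1.0), ("cable", 1.1)])
    row = out.iloc[0]
    assert row["n"] == 3
    assert row["mean"] == pytest.approx(1.0)
    assert row["sem"] == pytest.approx(0.1 / math.sqrt(3), rel=1e-9)


def test_aggregate_single_value_sem_undefined():
    out = aggregate([("ring", 0.8)])
    assert out.iloc[0]["n"] == 1
    assert math.isnan(out.iloc[0]["sem"])


def test_aggregate_zero_variance():
    out = aggregate([("patch", 0.5)] * 4)
    assert out.iloc[0]["sem"] == pytest.approx(0.0)
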