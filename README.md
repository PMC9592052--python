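# tpmquant

Ratiometric quantification of how strongly tropomyosin decorates each
class of F-actin structure — endocytic patches, actin cables and the
cytokinetic actomyosin ring (CAR) — in two-channel live-cell
fluorescence microscopy of fission yeast, where one channel carries a
tagged tropomyosin (e.g. mNG–Cdc8) and the other an F-actin reporter
(e.g. LifeAct–mCherry).

The package is for cell biologists who want a reproducible, scriptable
version of this measurement: it provides the supporting image
operations (calibrated TIFF stack I/O, average/maximum z-projection,
photobleaching correction, cross-correlation channel registration,
kymographs along the cell long axis), trainable per-pixel segmentation
of the structure classes, the decoration-ratio statistic itself, and a
ground-truthed synthetic microscopy generator used to validate the
whole chain end to end.

## The statistic

For a structure ROI the *decoration ratio* is

```
    roi_tpm − cyt_tpm       cell_factin − out_factin
r = ─────────────────────  ×  ───────────────────────
    roi_factin − cyt_factin    cell_tpm − out_tpm
```

where `roi_X` is the trimmed mean over the ROI (darkest 10% of pixels
omitted; cable ROIs first eroded by 1 px), `cyt_X` the trimmed mean
over the parent cell's cytoplasm (brightest 10% omitted), `cell_X` the
mean over the whole cell and `out_X` the mean extracellular background.
The first factor is the structure's tropomyosin/F-actin signal above
the cytoplasmic pools; the second normalises away the two reporters'
expression levels and acquisition gains.  A structure whose tropomyosin
recruitment matches its F-actin content scores ≈ 1, an undecorated
structure ≈ 0, and the value is invariant to rescaling or offsetting
either channel.  Per class the pipeline reports n, mean and
s.e.m. (sample sd / √n; undefined for n = 1).

## Worked example

Generate three synthetic fields of rod-shaped cells whose true
decoration ratios are 0.14 (patches, half of them carrying no
tropomyosin at all), 0.97 (cables) and 0.95 (rings), then quantify them
with ground-truth masks:

```python
import pandas as pd
from tpmquant import (
    OpticsNoiseModel, SceneConfig, detect_cells, project,
    quantify_image, render_scene, sample_scene, summarize,
)

config = SceneConfig(decoration_ratio={"patch": 0.14, "cable": 0.97, "ring": 0.95},
                     ring_fraction=0.5)
optics = OpticsNoiseModel(n_zplanes=1)          # single plane, default PSF + noise

tables = []
for i in range(3):
    scene = sample_scene(config, seed=i)
    stack, truth = render_scene(scene, optics)   # two-channel image + class map
    projected = project(stack, mode="average")
    cells = detect_cells(truth)                  # instances, clumps flagged
    tables.append(quantify_image(projected, truth, cells))

print(summarize(pd.concat(tables)).to_string(index=False,
                                             float_format=lambda v: f"{v:.3f}"))
```

```
class  n  mean   sem
cable 34 0.997 0.014
patch 89 0.120 0.007
 ring  6 0.998 0.006
```

Cables and rings recover their high decoration settings; the patch
class mean sits a little above half the nominal 0.14 because only half
of the generated patches carry tropomyosin (the per-ROI ground-truth
mean for this draw is 0.08), with a small upward bias from the
whole-cell normalisation that is analysed in `docs/methods.md`.

The same run is available from the shell:

```bash
tpmquant simulate --seed 0 --out data/ --n-images 12
tpmquant quantify data/ run/            # writes rois.csv + summary.csv
tpmquant pipeline config.yaml run/      # fully configured, manifest-reproducible
```

`run/rois.csv` lists every ROI with its areas, all channel means and an
explicit exclusion reason when a ROI fails the reference-signal
preconditions; `run/summary.csv` holds the per-class aggregates; and
`run/manifest.json` lets `tpmquant.pipeline.run_from_manifest`
reproduce the tables byte for byte.

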