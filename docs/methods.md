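# Methods

## Measurement model

The pipeline quantifies tropomyosin recruitment onto three F-actin
structure classes in two-channel fluorescence images of fission-yeast
cells.  Both reporters are assumed to have (i) a diffuse cytoplasmic
pool, uniform within a cell, and (ii) a structure-bound component whose
intensity is proportional to local polymer content.  Under that model
the per-ROI statistic

r = [(roi_tpm − cyt_tpm) / (roi_factin − cyt_factin)] ×
    [(cell_factin − out_factin) / (cell_tpm − out_tpm)]

estimates the ratio of tropomyosin recruitment to F-actin content on a
structure, normalised so that it is independent of the two channels'
expression levels, exposure and gain.  Cytoplasm subtraction uses the
parent cell's own cytoplasm pixels, because the diffuse pool varies
from cell to cell; the extracellular background is taken over all
outside pixels of the field, because it is a property of camera and
medium, not of a cell.  "Whole-cell" means the untrimmed mean over all
pixels of the cell instance, structures included.

Robustness devices in the measurement, and why they exist:

- **1-px erosion of cable ROIs** (3×3 square element).  Cables are a
  few pixels wide, so their boundary pixels are part cytoplasm; eroding
  the measured set keeps only interior pixels.  If erosion empties a
  ROI the original set is kept and the ROI flagged
  (`erosion_fallback`), never silently dropped.
- **One-sided 10% trims.**  The darkest `floor(0.10·n)` structure
  pixels (blur-attenuated edges) and the brightest `floor(0.10·n)`
  cytoplasm pixels (spill from adjacent structures) are omitted,
  per channel independently.  With n < 10 nothing is discarded.
- **Explicit exclusions.**  A ROI whose F-actin signal above cytoplasm,
  or whose whole-cell tropomyosin signal above background, is not
  positive (tolerance 10⁻⁶ × background) carries no usable reference
  and is reported with an exclusion reason rather than contributing a
  meaningless ratio.
- **Minimum ROI area of 5 px** (the PSF-core footprint).  No real
  structure can image smaller than the PSF; single-pixel components in
  classifier output are noise, and because they are *selected* for
  channel-2 brightness their ratios can reach 20–50.

Per class the pipeline reports n, mean, and s.e.m. = sample sd
(n−1 denominator)/√n, with the s.e.m. reported as undefined (NaN) for
n = 1 rather than 0.

## Segmentation

Per-pixel classification follows the trainable-segmentation approach:
a multiscale filter bank (raw intensity; Gaussian mean, gradient
magnitude and Laplacian at σ ∈ {1, 2, 4, 8} px; difference-of-Gaussians
between consecutive scales) feeds a 100-tree random forest.  Patches
plus the two background classes are detected on the F-actin channel;
cables and rings on the tropomyosin channel; the per-channel maps merge
under the fixed precedence ring > patch > cable > cytoplasm > outside
(rarest and brightest class wins).  When training, each channel's
classifier is shown the *other* channel's structure pixels labeled as
cytoplasm, so that e.g. a bright cable in the F-actin image is learned
as elongated background rather than being mistaken for a patch.

Training is deterministic and invariant to the order of training
images: labeled pixels are brought into a canonical (lexicographic)
order before seeded per-class subsampling, and the forest uses a fixed
random state.  Held-out accuracy on 20% of the annotations is reported
on the fitted estimator.

Two post-processing rules operate on class maps:

- **Ring-fragment refinement.**  The filter bank is isotropic, so short
  bright cable segments are sometimes classified as ring.  A real CAR
  spans the cell diameter (~3.5 µm ≈ 50 px at 69 nm/px) times its band
  thickness; ring components under 50 px are therefore physically
  impossible rings and are reassigned to cable.
- **Clump flagging.**  Cell instances are 8-connected components of
  non-outside pixels with area ≥ 500 px²; an instance larger than
  2.5 × the median instance area is flagged as a clump and excluded
  from quantification (a touching mother–daughter pair, at ~2× median,
  is deliberately kept as one analysable instance).

A deterministic rule-based fallback (`threshold_segment`) exists for
data without annotations: robust global threshold for the cell mask,
per-blob half-max thresholding with shape filters for patches, and
excess-intensity candidates split into cable vs ring by per-pixel
structure-tensor orientation relative to the host cell's long axis.

## Synthetic scenes

The generator emulates fields of rod-shaped cells imaged at
69 nm/pixel: capsules of radius 1.75 µm and length 7–14 µm placed
without overlap, containing tip-biased diffraction-limited patches
(label radius 0.25 µm, 3–8 per cell), 1–3 Gaussian-profile cables
roughly parallel to the long axis (0.3 µm wide), and in 15% of cells a
medial ring band (0.3 µm thick) — the approximate incidence of
dividing cells.  Deliberate clumps (rows of 3–5 touching cells) are
generated at a configurable rate so clump filtering is testable.

Channel 2 structure amplitude is `decoration_ratio[class] ×` channel-1
amplitude `× expression_scale`, applied *above* the cytoplasm level,
and only a configurable fraction (default 0.5) of patches carry any
channel-2 signal.  The recorded ground truth therefore gives each
structure a per-ROI true ratio (0 for undecorated patches), and
"truth" in every recovery experiment is the mean of those per-ROI
values, not the nominal class setting.

Intensity scales are free parameters of the instrument, chosen once
for realism: outside 50 photons, cytoplasm 400 photons above outside,
cables 150–250, patches 400–800 and rings 300–500 photons above
cytoplasm.  The bright diffuse pools relative to structure contrast
put the statistic in its near-unbiased regime — which must be the
regime of the real measurement, since fully decorated structures score
≈ 1 there.  Optics defaults are computed from the imaging setup the
data emulate: lateral PSF σ = 0.21 λ/NA ≈ 74 nm ≈ 1.1 px (510 nm
emission, NA 1.45), axial FWHM ≈ 0.5 µm ≈ 0.55 planes at 0.4 µm
z-steps, 16 planes.  Noise is Poisson shot noise on expected photons
plus Gaussian read noise (σ = 2 counts); per-pixel variance over
repeated renders equals mean/photons_per_count, which a test checks.

What the generator does *not* emulate: cell-to-cell expression
variability beyond the global channel scale, intracellular organelles
and vacuoles (dark cytoplasm regions), spectral bleed-through, uneven
illumination, EMCCD excess noise, and structure dynamics beyond a
constant-velocity mode used for kymograph tests.  Passing tests
therefore demonstrate correctness of the measurement chain under the
stated model, not robustness to every real-data artifact.

## Validation design

- **Exact oracles.**  The trimmed mean is checked against an
  independent sort-discard-average implementation (property test plus
  1000 random lists), erosion against a brute-force 3×3 neighbourhood
  check, registration against 50 known integer shifts, and the
  worked-example cell against hand arithmetic (r = 8/9) to 10⁻¹².
- **Parameter recovery** runs the generator's single-plane *unblurred*
  mode with the default Poisson and read noise, 5 fields × 6 cells
  (~30 cells) per condition, ratios 0.1–1.0 plus the
  patch 0.14 / cable 0.97 / ring 0.95 condition.  Unblurred rendering
  is used deliberately: with PSF blur and purely *geometric* masks the
  statistic acquires a toward-one bias of +0.05…+0.10 at low ratios,
  because blur-dimmed rim pixels inside the geometric cell boundary
  depress the trimmed cytoplasm reference.  Classifier-derived masks
  place the boundary at half-max and do not show this, so the blurred
  regime is validated through the trained-segmentation arm and the
  segmentation gate instead.  Even unblurred, two small inherent biases
  remain and are visible in the reported numbers (cable ≈ +0.05 at mid
  ratios): the one-sided trims shift each channel's numerator by
  ≈ +0.195 σ_pixel on noise-flat regions, and the whole-cell
  normalisation includes structure signal.
- **Segmentation gate** at full default 2D optics: training on two
  fields, scoring two held-out fields (accuracy, per-class IoU), and
  clump-flag sensitivity over 12 deliberate clumps.
- **Determinism.**  Scenes, datasets and whole pipeline runs are
  reproducible byte-for-byte from their seeds/manifests; tests assert
  identical CSV bytes across a manifest rerun.

Problem sizes (5 fields per condition, 320–512 px test fields, 2–3
training images) are the package's validation defaults, chosen to make
the class means stable (s.e.m. ≲ 0.01–0.03) while keeping the full
suite quick on a laptop.

## Numerical and interface conventions

- Arrays are (T, C, Z, Y, X); pixel coordinates are 0-based (row, col);
  8-connectivity throughout.
- Registration reports the displacement (dy, dx) of the moving image
  relative to the reference; the aligned raster is shifted by −shift,
  with wrapped/filled edge pixels masked out of all downstream
  statistics.  Estimates beyond `max_shift` are clamped with a warning.
  Constant images raise ("no registration signal").
- Bleach correction: `simple_ratio` rescales every frame mean to frame
  0 (exactly idempotent); `exponential_fit` fits a·e^(−kt)+c to frame
  means with non-negative bounds and falls back to simple_ratio with a
  warning if the fit fails; a constant series short-circuits to k = 0.
- Kymographs sample bilinearly at unit steps along the line, averaging
  over an odd perpendicular width (default 5 px); the long axis comes
  from the mask's second moments with a canonical orientation (angle in
  [0, π), first endpoint at smaller x).  Ridge velocity is per-column
  argmax with sub-pixel parabolic refinement and a least-squares slope.
- Quantification always runs on the *average* z-projection; maximum
  projection is reserved for display and kymographs.  Whether bleach
  correction precedes projection is configurable; the default order for
  time series is projection-last.
- TIFF axis order is taken from the JSON sidecar or explicit override —
  never guessed; a missing pixel size is an error naming the field.

## Known limitations

- Ring-vs-cable discrimination rests on geometry (orientation, size),
  not appearance; heavily tilted or partially assembled rings may be
  scored as cables.
- The decoration ratio inherits the biases of its definition: the
  whole-cell normalisation includes structure signal (≈ +2–5% for
  structure-dense cells), and trimming biases numerators upward at very
  low signal-to-noise.  Between-class comparisons at similar SNR are
  unaffected; absolute values below ~0.1 should be read with that in
  mind.
- Classification is 2D on projections; overlapping structures in z are
  resolved by class precedence, not separated.
- No flat-field or dark-frame calibration, deconvolution, drift
  correction, or time-lapse instance tracking.
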