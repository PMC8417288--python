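# Methods

This note documents the models, conventions and numerical choices behind
`octafract`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Scan model and coordinates

An en face angiogram is a single-channel image whose intensity is
proportional to decorrelation (flow). The default geometry is a 3×3 mm
macular scan sampled 304×304 (pixel pitch ≈ 9.9 µm), fovea at the grid
centre `((N−1)/2, (N−1)/2)`, 0-based row-major coordinates with origin at
the top-left. Intensities are calibrated to [0, 1] by dividing by the dtype
maximum (not the per-image maximum) so images from different acquisitions
remain comparable. A signal-strength index below 40 raises a report flag but
never aborts the analysis: low signal is an acquisition-quality issue, not
an analysis error.

## Binarization

Foreground is `intensity > t` with `t` chosen by between-class-variance
maximization (Otsu) on a 256-bin histogram spanning the fixed [0, 1] domain.
Two details matter for reproducibility: the histogram domain is fixed rather
than the per-image range (otherwise bin edges — and hence borderline pixels —
shift between nearly identical images), and the threshold is the upper edge
of the cut bin so that an exact two-level image splits exactly. A constant
image yields an all-background mask with a warning; a foreground fraction
above 60% warns about probable inverted contrast.

## Local fractal dimension

For each pixel, a `window_px = 33` square window is centred on it (clipped
at the image border) and box-counted at sizes `{16, 8, 4, 2}` px: each scale
tiles the clipped window with boxes anchored at the window's top-left
corner, discarding trailing partial boxes (floor tiling), and counts boxes
containing foreground. The FD is the unweighted least-squares slope of
log N(s) against log(1/s), clipped to [0, 2]; a window without foreground
gets FD 0 by convention.

Floor tiling is load-bearing: counting partial boxes inflates the
small-count scales and biases a filled window's slope to ~1.67, whereas
floor tiling measures exactly 2.0 for a filled window and exactly 1.0 for a
one-pixel line with power-of-two box sizes. At the image border the per-scale
tiled regions can differ slightly; a scale whose tiled region happens to
contain no foreground contributes log 1 = 0, keeping the regression finite.
The implementation (integral-image occupancy, vectorized over all pixels) is
tested to 1e-9 against an independently coded brute-force slicing oracle,
including border pixels.

Window and box sizes are conventions, not measurements: 33 px ≈ 0.33 mm
spans several intercapillary distances while remaining local, and powers of
two give a clean log-log ladder. Both are exposed in `AnalysisConfig`;
metric values shift with them, which is why the normalized ratio (below) and
not the raw FD drives classification.

## Normalized ratio and bands

The ratio map divides the FD map by its own maximum (warning and all-zero
output if the image has no foreground). Self-normalization makes the band
thresholds robust to the window choice. Bands form a declared partition:
large spacing [0, 0.3), small spacing [0.3, 0.7), vessel [0.7, 1.0] — the
half-open convention resolves the boundary ambiguity of quoting the
intervals as "0.0–0.3" and "0.3–0.7". Band percentages over a region use the
region's pixel count as denominator and sum to 100 exactly up to float
rounding. The default region is the whole image (matching the published
vessel-density formula); a 1–2.5 mm-diameter parafoveal annulus
(`inner/2 ≤ d < outer/2` on pixel-centre distances) is reported alongside,
since it is not documented over which region the published spacing
percentages were taken.

## FAZ measurement

The reported FAZ is the connected no-flow component containing the fovea:
the binarized vessel set is morphologically closed with a 10-px disc
(≈ 0.1 mm, the intercapillary-spacing scale, so the foveal component cannot
escape through normal capillary gaps), the avascular component containing
the fovea centre is taken (seeding from the nearest avascular pixel within
5 px if the centre itself is vessel; FAZ is reported *absent*, not zero,
when none exists), eroded by 1 px to compensate the closing's hull
overshoot between the innermost capillaries, and converted to mm² by the
pixel area. The image border is treated as avascular during the erosion so
a fully avascular image keeps its full area. On phantoms this recovers
carved discs of 0.2–0.8 mm² within ±8%.

A class-map variant (`measure_faz`) is provided but not used for reporting:
the 33-px fractal window dilates the vessel class into the FAZ by a large
fraction of the window radius, shrinking the apparent FAZ by ~50% — the
no-flow (mask-based) measurement is the faithful one.

## Projection-artifact removal

The deep plexus is contaminated by a ghost of the superficial vasculature
(decorrelation of light that crossed flowing superficial blood), modelled as
additive and linear in the SCP image with a single whole-image scale, then
clipped to the intensity ceiling. The removal subtracts `α·SCP` from the DCP
and clips to [0, 1] (clipping at zero slightly raises background statistics;
documented, not corrected).

α is estimated as a conditional-median amplitude: split the SCP into flow
and background populations by its Otsu threshold, then

    α = (median DCP | SCP flow − median DCP | SCP background)
        / (median SCP | SCP flow − median SCP | SCP background).

The classical least-squares slope cov/var is biased low once the artifact
saturates pixels at the ceiling (measured −0.04 to −0.14 at injected scales
0.5–0.8), and restricting it to unsaturated pixels replaces that with a
truncation bias (up to −0.36). Medians ignore the saturated tail and the
DCP's own vasculature as long as deep flow covers less than half of each
SCP population, which holds for en face angiograms. The LS slope and the
zero-lag Pearson correlation are still computed and reported as
diagnostics; α is clamped to [0, 1.5] with a warning and a report flag.
On phantoms the estimator recovers injected scales 0.3/0.5/0.8 within
±0.01, and removal strictly reduces |corr(DCP, SCP)|.

## Synthetic phantoms

The generator emulates exactly the structures the metrics assume, with
exact ground truth and bit-reproducibility from a single seeded stream per
phantom:

- **FAZ**: a carved disc of the requested physical area (default 0.42 mm²,
  the normative value); an irregular-boundary option perturbs the radius by
  smooth random harmonics for altered-FAZ scenarios (its realized area is
  then measured from the region, not assumed).
- **Capillary mesh**: the skeleton of median-thresholded smoothed Gaussian
  noise — a connected curvilinear net. Skeleton coverage is ≈ 0.19/σ, so the
  smoothing length is iteratively rescaled until coverage outside the FAZ is
  within 5% of the target. Default coverage 0.12: at ~10 µm pixels a ~1-px
  capillary calibre and 50–100 µm intercapillary spacing give ~12% area
  coverage. Keeping the net intact (no pixel-level thinning) preserves loop
  connectivity; a union-and-thin fallback exists for dense targets and loses
  some curvilinearity.
- **Large vessels**: six dilated correlated random walks (default width
  4 px ≈ 40 µm) entering from the border and steered tangentially around
  the FAZ.
- **Dropout**: discs of radius 6 px erase capillary pixels (large vessels,
  identified by width via morphological opening, are preserved) until
  exactly the requested fraction of capillary pixels is gone; the final
  disc is truncated, so the fraction is exact and nested across increasing
  dropout at a fixed seed.
- **Rendering**: vessel 0.8 / background 0.1 plus Gaussian noise
  (default sd 0.05), clipped to [0, 1].
- **Projection artifact**: `DCP ← clip(DCP + scale·SCP)`. The full SCP
  image is projected (not only its large vessels): the contamination is
  then exactly linear in the SCP, which is what a single scaling-factor
  subtraction can and should undo, and what makes recovery testable.

What the phantoms do **not** model: OCT speckle statistics, flow-dependent
decorrelation, motion/blink artifacts, segmentation errors, retinal edema
shadowing, or the anatomy of real lesions (dropout discs are a geometric
stand-in for capillary non-perfusion). Passing phantom tests therefore
demonstrates the correctness and calibration of the *computation*, not
clinical validity of the metrics on device images.

## Normative comparison

Per-layer z-scores `(measured − mean)/sd` against a reference shipped as an
editable YAML (a published normative cohort for this scan protocol; device-
and population-specific, so replace it for other instruments). Whether the
published spread is SD or SEM is not stated by its source; it is treated as
SD, and the YAML is the single place to change that. |z| > 2 is flagged as
outside normal.

## Problem sizes and determinism

All validation runs use the native 304×304 geometry; batches are 50 phantoms
for the partition property, 10 seeds × 3 scales for projection recovery,
and 6 dropout levels for the disease-direction property — sizes chosen so
the full suite exercises every stage end-to-end in well under half an hour
on one core. Every stochastic component draws from an explicit
`numpy.random.Generator`; identical spec + seed + config reproduce
byte-identical reports.

## Known limitations

- Band percentages depend on the self-normalizing maximum; on images with
  no dense vessel region the ratio rescales and band values shift.
- Healthy phantoms yield almost no large-spacing pixels (the mesh is
  spatially uniform); real retinas have genuinely sparse regions, so
  absolute phantom band values are not comparable to clinical normative
  values — only directions and recoveries are validated.
- The FAZ hull-offset erosion is a 1-px discretization compensation
  calibrated to the phantom's capillary scale; at far coarser pixel pitches
  it would need revisiting.
- Projection removal assumes a global scalar coupling; spatially varying
  artifacts (e.g. under edema shadowing) are out of scope.
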