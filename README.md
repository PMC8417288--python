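# octafract

Quantitative analysis of OCTA en face angiograms by local fractal dimension:
per-pixel vessel mapping, three-band capillary-dropout classification, foveal
avascular zone (FAZ) measurement, parafoveal-ring metrics, and removal of
superficial-vessel projection artifacts from the deep capillary plexus — plus
a synthetic phantom generator that provides exact ground truth for validating
every stage.

## Who this is for

Retinal imaging researchers who want device-independent OCTA metrics.
Built-in instrument software reports flow density with proprietary,
irreproducible processing; this package implements the whole chain in the
open, from raw single-channel en face images (TIFF/PNG, e.g. 304×304 px over
a 3×3 mm macular scan) to per-eye metric reports.

## The method

1. **Binarize** the calibrated flow image by between-class-variance (Otsu)
   thresholding.
2. **Local fractal dimension (FD).** For every pixel, a 33-px window is
   box-counted at box sizes {16, 8, 4, 2}; the FD is the least-squares slope
   of log N(s) vs log (1/s). FD ≈ 2 in space-filling capillary mesh, ≈ 1 on
   an isolated vessel, 0 in avascular regions.
3. **Normalized ratio** = FD / max(FD over the image), in [0, 1] — an
   apparent probability index of vessel presence.
4. **Three-band classification** of the ratio:
   *vessel* [0.7, 1.0], *small-vessel spacing* [0.3, 0.7), *large-vessel
   spacing* [0.0, 0.3). Vessel density and the two spacing percentages are
   the band shares of the analysis region (whole image, and a 1–2.5 mm
   parafoveal ring); they sum to 100 by construction.
5. **FAZ area**: the connected no-flow region at the fovea after sealing
   intercapillary gaps by morphological closing at the intercapillary scale
   (10 px ≈ 0.1 mm), in mm².
6. **Projection-artifact removal** (deep layer): the zero-lag normalized
   cross-correlation between SCP and DCP is computed, a whole-image scaling
   factor α is estimated by a saturation-immune conditional-median amplitude,
   and α·SCP is subtracted from the DCP before quantification.
7. **Normative comparison**: z-scores per metric against a per-layer
   reference (shipped as an editable YAML).

## Worked example

```python
from octafract import PhantomSpec, generate_phantom, analyze_eye

# healthy 3x3 mm phantom pair: FAZ 0.42 mm^2, 12% capillary mesh, no dropout
scp, dcp, truth = generate_phantom(PhantomSpec(seed=42))
report = analyze_eye(scp, dcp)
m = report.scp.metrics_whole
print(f"SCP vessel density {m.vessel_density_pct:.1f}%  "
      f"small spacing {m.small_spacing_pct:.1f}%  "
      f"large spacing {m.large_spacing_pct:.1f}%")
print(f"SCP FAZ {report.scp.faz_area_mm2:.3f} mm^2 (truth {truth.faz_area_mm2})")
```

prints

```
SCP vessel density 70.4%  small spacing 27.8%  large spacing 1.8%
SCP FAZ 0.444 mm^2 (truth 0.42)
```

The three percentages partition the image (sum 100); the measured FAZ is
within the ±10% discretization/sealing budget of the carved 0.42 mm² disc.
Disease phantoms (`dropout_fraction=0.4`) show the expected direction: vessel
density falls by ~20–25 percentage points while both spacing bands grow.

Command line:

```bash
octafract phantom --seed 3 --out ph/            # phantom pair + ground truth
octafract analyze --scp ph/scp.tiff --dcp ph/dcp.tiff --fov-mm 3 --out out/
octafract batch --manifest eyes.csv --out cohort/
```

`analyze` writes a per-eye JSON report, colored ratio-contour and
red/yellow/blue class-map PNGs (red = vessel, yellow = small spacing,
blue = large spacing), and a 32-bit float TIFF of the ratio map.

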