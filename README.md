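# cvchroma

Photo-based quantification of crystal-violet-stained biofilm.

## The problem

Biofilm on a material surface is routinely stained with crystal violet (CV)
and quantified by extracting the dye into SDS solution and reading
absorbance at 590 nm. That works for small coupons but not for large or
irregular products. An alternative is to quantify the stain *optically*,
straight from a photograph: the more biofilm, the stronger the violet
tint, and the further the specimen's colour moves on the CIE 1931
chromaticity diagram. `cvchroma` implements that workflow for
microbiologists and materials scientists who photograph stained specimens
under fixed illumination and want a reproducible colour-shift number per
condition.

## The method

Each photograph's region of interest (the "measurement range") is reduced
to per-channel 256-bin RGB histograms. The count-weighted mean colour
(R, G, B), each channel normalized to [0, 1] and by default sRGB
gamma-decoded, is converted to CIE XYZ tristimulus values with the D65
linear-sRGB matrix

```
| X |   | 0.4124  0.3576  0.1805 | | R |
| Y | = | 0.2126  0.7152  0.0722 | | G |
| Z |   | 0.0193  0.1192  0.9505 | | B |
```

and projected to chromaticity

```
x = X / (X + Y + Z),   y = Y / (X + Y + Z)
```

Replicates of one condition (substrate × immersion time) are summarized by
mean and sample SD of (x, y), and the biofilm-induced colour shift between
two conditions is

```
ΔC = sqrt((x₁ − x₂)² + (y₁ − y₂)²)
```

the Euclidean distance between the two group means on the xy plane.
CIELAB L\*a\*b\* coordinates and the ΔE\*ab distance are computed alongside.
A synthetic-image generator (uniform stained patch + Gaussian sensor noise,
built by exactly inverting the forward colour path) makes the entire
pipeline testable with known ground truth.

## Worked example

`examples/02_simulate_and_analyze.py` simulates two replicate groups whose
true chromaticity difference matches the titanium staining magnitude, then
recovers it:

```
group summaries (mean ± sample SD of chromaticity):
  Ti only   n=10  x = 0.32370 ± 0.00010  y = 0.34247 ± 0.00012
  Ti day 3  n=10  x = 0.31709 ± 0.00012  y = 0.33345 ± 0.00022

recovered ΔC = 0.011184   (ground truth 0.011161)
```

The group means are the coordinates one would plot on the chromaticity
diagram; the recovered ΔC agrees with the known truth to ~2 × 10⁻⁵, far
below the shift a 3-day biofilm produces, so differences of that size are
well resolved. See also `examples/01_color_conversion.py` (the colour math
step by step) and `examples/03_roi_histograms.py` (ROI histograms).

## Command line

```
cvchroma simulate --spec exp.json --out sim/          # synthetic fixtures
cvchroma analyze  --sheet sim/sample_sheet.csv --out results/ --plot
cvchroma compare  --summaries results/summaries.csv --baseline "Ti only"
```

`analyze` consumes a sample sheet (CSV: `specimen_id, condition,
image_path`, optional per-row ROI `r0,r1,c0,c1` or `mask_path`) and writes
measurements, group summaries, and pairwise-ΔC CSVs, a JSON run manifest,
and optionally an xy scatter plot. Coordinates are 0-based (row, column)
with half-open rectangles.

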