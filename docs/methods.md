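# Methods

## Pipeline

A specimen photograph plus a region of interest (ROI) is reduced to a
single chromaticity point in four steps:

1. **Histogram.** All ROI pixels are binned into per-channel 256-bin
   histograms; the count-weighted mean of bin values, divided by 255,
   gives the mean encoded RGB. This mirrors the ImageJ-histogram workflow
   the assay was designed around, and equals the direct per-pixel mean
   exactly.
2. **Linearization.** Consumer cameras store gamma-encoded values while
   the conversion matrix below is defined on linear light, so the mean
   channels are passed through the piecewise sRGB EOTF (threshold 0.04045,
   linear slope 1/12.92, power 2.4 with offset 0.055). The source
   procedure is silent on this step, so it is a per-run switch
   (`linearize`, default on) recorded in every output row; gray colours
   are unaffected by the choice, and for the near-neutral colours of
   stained metal coupons the effect on *relative* shifts is small.
3. **XYZ and chromaticity.** The linear RGB vector is multiplied by the
   D65 linear-sRGB matrix (rows 0.4124/0.3576/0.1805, 0.2126/0.7152/0.0722,
   0.0193/0.1192/0.9505) and projected to x = X/(X+Y+Z), y = Y/(X+Y+Z).
   The projection is scale-invariant, so illumination intensity cancels;
   chromaticity is undefined for pure black, which raises an error (mean
   mode) or is excluded with a logged count (per-pixel mode).
4. **CIELAB.** L\*a\*b\* uses the CIE 1976 cube-root companding with the
   6/29 threshold. The reference white defaults to the matrix row sums
   (0.9505, 1.0000, 1.0890) so every conversion is internally consistent
   with the same matrix; its chromaticity, (0.312716, 0.329002), is where
   all gray inputs land.

Replicate groups are summarized by the arithmetic mean and *sample*
standard deviation (n − 1 denominator; with a single replicate the SD is
reported as 0 and flagged). Conditions are compared by
ΔC = √((x₁−x₂)² + (y₁−y₂)²) between group means, reported to 5
significant digits; ΔE\*ab (CIE76) is available as a companion statistic.

### Reduction order

Averaging colour before the nonlinear chromaticity projection
(*mean-then-convert*, the default, faithful to the histogram workflow) and
averaging per-pixel chromaticities (*per-pixel*) are both provided; the
mode is recorded in outputs. For near-uniform stained patches they agree
to well below measurement noise; they genuinely differ on multi-modal
ROIs, which the tests pin with a two-colour fixture.

## Synthetic specimen generator

The generator emulates the photographic setup — a near-uniform stained
patch under fixed illumination, shot with fixed exposure — not the
staining chemistry. Its model: a base colour constructed by exactly
inverting the forward path from a target chromaticity (x, y) and relative
luminance Y; optional radial vignetting (linear-light factor
1 − strength·(r/r_max)²); i.i.d. per-pixel per-channel Gaussian noise in
8-bit units; round-half-to-even quantization and clipping to [0, 255]
(clipping above 0.1 % of samples is logged).

Defaults are chosen to be realistic for the assay: luminance Y = 0.35 (a
mid-grey coupon under ring-light illumination), noise SD 5/255 (typical
consumer-camera sensor noise at low ISO), 64×64-pixel patches, and the
published titanium chromaticities (0.3237, 0.3425) → (0.3171, 0.3335) as
the canonical two-condition scenario — a true ΔC of 0.0112, the magnitude
a 3-day biofilm produces. The `staining_series` helper emulates
immersion-time designs by drifting chromaticity toward the lower left
(the direction increasing crystal-violet stain moves it), default
(−0.0022, −0.0030) per day.

Seeding: one master seed expands to per-image seeds as
`(master + 10007·index) mod 2³¹`, so any subset of images reproduces from
the master seed alone and repeated runs are byte-identical.

What the generator does **not** model: Poisson/shot noise, chroma
subsampling, illumination gradients beyond radial vignetting, specular
highlights, specimen texture, or staining chemistry. Passing recovery
tests therefore show the *computational* pipeline is unbiased and
resolves shifts of the published size under idealized imaging; they do not
validate camera calibration or staining reproducibility on real specimens.

## Numerical choices

- All conversions in double precision; 8-bit normalization divides by 255.
- The sRGB decode/encode branches are exact inverses except a ~2×10⁻⁵
  seam mismatch near the 0.04045 threshold inherent to the standard
  constants.
- Inversion to RGB solves the 3×3 system directly; a target whose implied
  linear channel leaves [0, 1] by more than 1×10⁻⁹ is rejected as out of
  gamut, naming the channel.
- Rectangle ROIs are half-open [r0, r1) × [c0, c1), 0-based (row, column);
  polygons include pixels whose centers fall inside (even–odd rule);
  boundary pixels follow matplotlib's path semantics.
- 16-bit images are rescaled by 255/65535 with round-half-to-even; JPEG
  inputs are accepted with a warning that chroma subsampling perturbs
  chromaticity.
- Output tables are sorted by condition and specimen id, making results
  invariant to sample-sheet row order; CSV floats use a fixed `%.10g`
  format so reruns are byte-identical.

## Design choices

- The default ROI, when a sample sheet row gives none, is a centered
  rectangle covering 60 % of each image dimension — a conservative stand-in
  for "the specimen minus its edges"; real analyses should supply explicit
  ROIs.
- The ΔC baseline defaults to the first condition in the sheet,
  conventionally the unstained/day-0 substrate.
- No hypothesis testing between groups is performed; ΔC is a descriptive
  effect size, and replicate counts in typical staining series are too
  small for distributional assumptions to add value here.
- No chromatic adaptation, ICC profiles, or CIEDE2000: the assay compares
  conditions photographed under one fixed illuminant, where a fixed matrix
  and Euclidean distances suffice.

## Limitations

- Absolute chromaticities from photographs differ from colorimeter
  readings (observed in practice as an offset with preserved trends); no
  cross-device reconciliation transform is attempted.
- Quantization limits single-image chromaticity accuracy to about 0.004
  in x and y for an 8-bit camera; replicate averaging reduces the noise
  component but not any shared bias.
- The pipeline assumes the ROI is the stained specimen; no automatic
  segmentation or flat-field correction is provided.
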