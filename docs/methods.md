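# Methods

## Color model

Input photographs are assumed to be plain 8-bit sRGB, as produced by a
phone camera with automatic exposure and white balance and no further
processing. Conversion to CIELAB uses the IEC 61966-2-1 piecewise transfer
function, the published 7-decimal sRGB→XYZ (D65) matrix, and the CIE 1976
L\*a\*b\* formulas with the D65 2°-observer white point
(Xn = 95.047, Yn = 100.000, Zn = 108.883). The f(t) threshold is kept as
the exact rational (6/29)³ for reproducibility. No ICC handling or
chromatic adaptation is performed; because exposure and white balance vary
per photograph and are not corrected, absolute b\* values are comparable
within one image but only approximately across images.

The inverse transform (needed by the synthetic generator) clips
out-of-gamut linear RGB to [0, 1] and reports a per-pixel flag rather than
raising; a 10⁻⁶ tolerance on the gamut test absorbs the roundoff of the
7-decimal matrix (reference white otherwise lands ~10⁻⁷ outside 1.0).
Tests hold the vectorized transform to ≤ 10⁻⁶ of an independently coded
scalar implementation; agreement with scikit-image is ~10⁻² because
skimage derives its matrix from chromaticity coordinates at higher
precision than the published 7-decimal constants.

## Segmentation

A pixel is positive iff b_lo < b\* < b_hi, strict bounds, defaults
(−20, −5). The bounds are strict and the lower bound is real: pixels bluer
than −20 are excluded by default. Whether that exclusion is ever desirable
is assay-dependent, so `extend_blue` drops the lower bound; both behaviors
are first-class. Segmentation is a pure per-pixel threshold — tests assert
exact equivalence with brute-force enumeration.

## Rounded-region detection

"Rounded areas of high positive density" is operationalized as:

1. morphological closing with a disk footprint (default radius 2 px) to
   seal noise dropouts;
2. 8-connected component labeling;
3. a size filter (default ≥ 50 px) and a circularity filter
   4πA/P² ≥ 0.6, with the Crofton perimeter estimate;
4. hole-filling **inside surviving components only**, after which the
   filled pixel count is the region's area;
5. assignment of each region to the grid cell containing its centroid
   (pixel-center-in-rectangle); at most one region is kept per cell
   (largest pixel count wins, extras logged), since each cell carries one
   inoculum.

Ordering matters in step 3–4: grid lines drawn under the plate are thin
closed loops around the cells, and filling holes *before* shape filtering
would flood every enclosed cell interior into one plate-sized blob whose
filled silhouette is roughly rectangular (circularity ≈ 0.78 — it would
pass). Computed on the unfilled component, the line network has a huge
perimeter and negligible area, so it is rejected immediately. A disk with
small interior dropouts is barely affected, and its missing interior is
restored by step 4.

Circularity 0.6 is a deliberately loose roundness bar: rasterized disks
score ≈ 0.9–1.0, noisy disks stay well above 0.6, while bars, line
fragments and ramified noise fall far below. The threshold, the minimum
area and the closing radius are all exposed parameters.

The manual fallback mirrors operator-placed circular masks
non-interactively: circles arrive as config/CLI parameters
(`{cell_id, cx, cy, r}`), and the positive pixels whose centers lie within
the circle (distance ≤ r) are counted. In `run_quantify`, manual masks
apply to cells the automatic path did not resolve.

## Calibration

One scalar converts pixels to millimetres: mm/px = physical length / pixel
length of a user-measured line (in practice the spacing between two grid
lines). Pixels are assumed square; anisotropy, lens distortion and
perspective are out of scope because acquisition is nadir-view on a fixed
support. Area follows as pixel_count · (mm/px)²/100 cm², formatted at 4
decimals in CSV output (well below one pixel's area at realistic scales,
and fixed so reruns are byte-identical).

## Screening analytics

The density matrix is a complete clones × (temperature, day) table of halo
areas, zero-filled for absent halos; duplicate (clone, condition) records
are rejected rather than silently aggregated. "Positive" means area
strictly > 0. Ranking on a chosen day: tier 1 = clones positive at *all*
requested temperatures (the fast, temperature-robust responders), tier 2 =
the rest; within a tier, descending total area over the requested
conditions, ties broken alphabetically — fully deterministic under row
shuffling. The hit rate is 100·k/n rounded half-away-from-zero to one
decimal, computed in exact integer arithmetic (tenths =
⌊(2000k + n)/(2n)⌋) so boundary cases never depend on float representation;
the rounded rate back-multiplies to the exact positive count for every
n ≤ 1000.

## Sequence utilities

ORF→protein length is bp/3 − 1 (one codon per residue, stop excluded).
Translation uses the standard genetic code (NCBI table 1) via Biopython,
with explicit internal-stop rejection; input is uppercased and U→T
normalised, anything outside ACGT rejected. The average molecular mass is
the sum of isotope-averaged residue masses plus one water (18.0153 Da),
reported in kDa to one decimal — the convention of gene-announcement
write-ups; the initiator methionine is included. The residue-mass table is
the standard average set; it agrees with Biopython's ProtParam table to
~10⁻³ Da per residue, far below the 0.1 kDa reporting precision.

## Synthetic plates

The generator emulates what matters to the measurement chain and nothing
more: a uniform agar background (default Lab (85, 0, 8), pale straw), thin
blue grid lines at known pixel and physical spacing, solid-disk halos
rendered from (L\*, 0, b\*) targets, an optional linear L\* ramp emulating
imperfect back-lighting (default 0), and additive Gaussian noise applied
in sRGB space after encoding, where sensor quantisation lives (default
σ = 2 on 8-bit channels). Defaults model the screening plates this package
was built around: a 4 × 5 grid of 13 mm cells at 100 px spacing
(0.13 mm/px; five 13 mm columns fit a 90 mm Petri plate), 12 positive
clones (LP1–LP12) and 8 negative controls (NG1–NG8), halo radii drawn from
10–40 px, halo L\* = 70.

Grid lines default to saturated marker blue (Lab (40, 10, −45)): drawn pen
lines are far bluer than diffuse dye halos, so they fall below the default
segmentation band — and when a wider band does capture them, the
circularity filter rejects the network (tested both ways). Randomly placed
halos keep their target b\* at least 1 unit inside the (−20, −5) band
because 8-bit quantisation perturbs rendered b\* by up to about ±0.5; a
target on the band edge would be legitimately unrecoverable. Ground truth
(centers, radii, rasterized pixel counts, areas from the implied
calibration, union mask) reflects the pre-noise scene; distinct seeds
change only the noise.

What the generator does **not** emulate — diffuse halo edges, agar
texture, specular highlights, condensation, perspective — bounds what
passing tests show: they validate the measurement chain (color transform,
thresholding, shape extraction, calibration, bookkeeping) under controlled
degradation, not the biological sharpness of real halo boundaries.

## Problem sizes and numerical choices

Validation uses 20 simulated 500 × 400 px plates per noise level with six
halos each — enough to cover the radius and b\* ranges while keeping the
whole suite fast. On those plates the pipeline recovers every halo
(precision = recall = 1) with zero area error at σ = 0 and worst-case
error under 5% at σ = 5; rendering the same physical scene at 1× and 2×
resolution changes measured cm² areas by < 1%. Degenerate inputs are
contracts, not crashes: an empty mask yields an empty region list, an
empty plate a zero matrix and 0.0% hit rate, a non-intersecting manual
circle or an inverted b\* band a ValueError.

## Known limitations

- Absolute b\* comparability across photographs is limited by the
  uncorrected automatic white balance of the camera.
- Overlapping halos are not deconvolved; the per-cell largest-region rule
  assumes one halo per inoculated cell.
- Halo edges are modelled as hard disk boundaries; on real plates the
  dye front is diffuse and the measured area depends on the band bounds.
- The physical grid spacing is a user input; no automatic grid detection
  is attempted.
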