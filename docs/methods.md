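# Methods

This note documents the models, parameters and design choices behind
`iopchart`, in the order the pipeline runs.

## Chart template

All pixel-based logic is driven by a single `ChartTemplate` describing the
printed form on a canonical 1800×1200 px raster (shipped as
`templates/german_24h_v1.json`; custom templates load from YAML/JSON). The
canonical size is the package's own choice — it gives integral pixel
spacing for every gridline. Key geometry:

- **Pressure axis** (piecewise linear, strictly decreasing in y):
  0 mmHg at y = 1150, 40 mmHg at y = 510 (16 px/mmHg), 80 mmHg at y = 190
  (8 px/mmHg). The halved density above 40 mmHg models the form's
  compressed upper scale. One pixel therefore corresponds to
  0.0625–0.125 mmHg, which bounds the quantization error of a perfectly
  read mark well below the 0.1 mmHg reporting resolution.
- **Time axis**: five slots per day at 10:00, 14:00, 17:00, 21:00, 00:00,
  with x offsets (0, 68, 120, 188, 240) px inside a 260 px day band —
  uneven because the slots are 4, 3, 4 and 3 hours apart. Midnight is
  charted at the end of its day band (it closes that inpatient day). Up to
  six day bands fit the frame.
- **Header**: fixed rectangles for the printed name label and the
  handwritten date field.

## Preprocessing

**Binarization** is Gaussian adaptive thresholding: a pixel is ink iff its
intensity falls below the Gaussian-weighted mean of its 27×27 neighborhood
minus an offset of 10 (borders replicated; kernel bandwidth from the
conventional ksize→σ rule, σ = 0.3·((w−1)/2 − 1) + 0.8). The 2-D window is
separable, so the implementation uses two 1-D passes; tests verify exact
per-pixel equality with a brute-force 2-D oracle.

**Frame detection** takes the contour with the largest *convex-hull* area.
Hull area, not enclosed area, because a frame with a corner cut off is an
open strip of ink whose raw boundary wraps around the strip and encloses
almost nothing. Before contour tracing the binary is cleaned by a
morphological opening that escalates downward — solid 3×3 block, then the
4-connected cross, then none — taking the first variant that leaves a
large-enough contour. The strong opening is needed because high-density
scan noise percolates into thin tendrils attached to the frame (which bias
its outline), while very thin printed strokes would not survive it.

The hull is simplified by Douglas–Peucker with a doubling tolerance
schedule starting at max(2 px, 0.1% of the perimeter) until at most six
vertices remain. A coarser start proved harmful: a tolerance on the order
of 1% of a chart-frame perimeter (~60 px) can swallow a true corner when
the hull is slightly chamfered there. The four longest polygon edges are
then refined by iterated PCA line fits on nearby contour points and
intersected pairwise. Completing corners from edge *lines* rather than
polygon vertices is what recovers a corner that is physically missing from
the scan; for an intact rectangle it reproduces the four vertices. The
result must pass a rectangle check (interior angles within 90° ± 10°, a
configurable tolerance) and cover ≥ 20% of the scan.

**Cropping** maps the four frame corners onto the canonical rectangle with
a projective warp rather than a plain crop, which keeps fixed-pixel
arithmetic valid for skewed scans; frames that fail the rectangle check
raise an error rather than being silently skipped.

## Extraction

**Gridline calibration**: Canny edges inside the plot band (header and
axis labels excluded) feed a Hough line transform restricted to ±5° from
vertical — horizontal rulings cannot vote. Peaks merge below a 20 px gap
and snap to the nearest template slot within 12 px, at most one line per
slot; fewer than three detected slots raises a calibration error.

**Color masks** threshold in HSV: blue (OD) hue 200°–260°, red (OS) hue
≤ 20° or ≥ 340°, both with saturation ≥ 0.30 and value ≥ 0.20. The hue
windows are disjoint, so the eye channels can never claim the same pixel.
White scan noise stays far below the saturation floor.

**Entry detection** looks at connected mask components within ±40% of the
local inter-slot spacing around each gridline. Components taller than
6 mmHg of vertical extent are treated as connecting-polyline strokes, not
marks; one morphological opening (disk radius 2) is attempted to split a
mark that a stroke merged into. The largest surviving blob per (line, eye)
becomes the entry; further blobs are kept but flagged `extra` (they appear
as false positives in evaluation, mirroring how surplus detections are
counted). The value is read at the median y of the mask pixels in a ±4 px
column band on the gridline, falling back to the blob centroid — the
median is unbiased when a polyline stub enters the window. Values are
reported at 0.1 mmHg resolution.

## Metadata

Date reading is segmentation → classification → parsing. Components in the
date field are delimiters if their area is under 25% of the median
digit-component area or their aspect ratio is flatter than 1:2; a digit
component wider than 1.6× the median width is flagged as two merged
digits. The default classifier is a multinomial logistic regression on
normalized 28×28 glyphs (MNIST-style centering), trained lazily in a few
seconds on ~1500 renders of the package's own stroke font with rotation,
wobble and stroke-width augmentation. The classifier is an interface; a
convolutional model trained on MNIST can be dropped in, but the default
keeps the repository free of downloads. Digits group into day.month.year
(German convention); two-digit years expand into 1950–2030; illegal
calendar dates raise an error.

Name extraction applies a `Surname, Givenname` regular expression (initial
uppercase including umlauts, lowercase tail) to the text of a pluggable
OCR engine. A Tesseract adapter is provided for environments that have it;
the default engine returns no text, so name extraction degrades to an
empty candidate list rather than a hard dependency. Extracted names are
pseudonymized (SHA-256 prefix) unless plain text is explicitly requested,
since chart headers identify patients.

## Synthetic data

`render_chart` draws the form exactly on the template geometry, records
each mark's nominal pixel as provenance, then simulates scanning: white
margin, optional top-right frame cut-off (up to 20%), rotation drawn
uniformly in a configurable range, additive Gaussian intensity noise, and
optional resolution rescaling. The default degradation — σ = 8 intensity
noise, ±3° rotation, ≤ 2 px mark jitter — is the reference noise model
used throughout the tests. Everything is driven by one seed;
identical seeds give byte-identical images.

The renderer emulates the features extraction depends on (colors,
geometry, stroke topology, handwriting-shaped digits, scan artifacts) but
not everything real scans contain: no staples, stains, pen corrections,
free-text annotations, or true handwriting variety, and both eyes' marks
are kept ≥ 1 mmHg apart at a slot because opaque ink renders coincident
marks literally indistinguishable. Passing round-trip tests therefore
demonstrates the pipeline's geometric and chromatic logic, not performance
on arbitrary clinical archives.

`simulate_cohort` draws, per patient: T_avg ~ N(15.2, 4.0²) and
IOP_var ~ N(6.9, 4.2²), truncated to physiologic bounds (profiles re-drawn
up to 100 times so that all five values stay in 0–80 mmHg); a peak slot
from a discrete wrapped-normal over the slot hours centered on 10:00 with
σ = half the 8.4 h acrophase spread; five slot values
T_avg + IOP_var·s with the fixed shape s = (0.55, 0.15, −0.05, −0.45,
−0.20) rotated so its maximum lands on the peak slot — the shape has zero
mean and unit range, so the realized mean equals the drawn T_avg exactly
and the realized range the drawn IOP_var (trough at 21:00 when the peak is
at 10:00, matching the observed diurnal pattern); small uniform wobble on
the non-extreme slots only; MAP ~ N(103.9, 12.7²), calibrated from
MOPP = ⅔(MAP − T_avg) so the cohort's MOPP averages ≈ 59 ± 9 mmHg; and a
progression label from a Bernoulli whose logit is the prevalence baseline
(42%) plus the association strength times the standardized IOP variables —
zero association by default, reflecting the null finding the statistics
layer is designed to reproduce. No within-day covariance structure beyond
peak/trough placement is claimed; the construction exists for testability.

## Evaluation

Matching is slot-exact: a detection can only match the truth entry at its
own (eye, slot); among several detections at one slot the nearest value
wins and the rest are false positives; unmatched truths are false
negatives. With at most one truth entry per slot this greedy rule is
assignment-optimal, which a brute-force enumeration oracle confirms on all
small charts. Value tolerance plays no role in matching — it only enters
the mean-distance metric, keeping detection errors and reading errors
separable. Aggregation follows the defining identities
fp_rate = FP/curve ÷ entries/eye (likewise FN) and
relative error = mean distance ÷ mean true value; the CLI prints rates as
percentages at two decimals.

## Statistics

`summarize_profile` computes T_max, T_min, T_avg, IOP_var and the
acrophase — defined as the slot at which the session's peak IOP was
reached, ties broken by the earliest slot; with only five unevenly spaced
measurements per day a cosinor fit is not identifiable, which is why the
argmax definition is used. The `outpatient` slot filter keeps 10:00,
14:00 and 17:00, enabling 24-hour vs. office-hours comparisons on the same
patients. MOPP uses MAP = diastolic + pulse pressure/3 (the standard
estimate; the defining text leaves MAP unspecified).

Acrophase alignment rotates each complete 5-slot profile circularly so its
peak lands on a reference slot (default 10:00) before averaging; circular
shifting is the package's choice for handling day boundaries. Alignment
can only raise the peak of the mean curve, which the tests assert on
simulated cohorts with spread acrophases.

Cutoff contingency uses strict inequality (value > cutoff ⇒ test-positive;
"above" at exact equality counts negative), fills the 2×2 table and the
sensitivity/specificity ratios, and reports NaN with a warning when a
class is absent. ROC curves and trapezoid AUC delegate to scikit-learn
(ties grouped into single threshold steps); an independent hand-rolled
threshold sweep cross-checks them in the tests. A helper excludes
IOP_var < 5 mmHg before ROC analysis, following the historical convention
that only variations above 5 mmHg signal progression. Standard inferential
tests (t, χ², Spearman, KS) are deliberately left to general statistics
packages.

## Problem sizes and numerical choices

The round-trip properties run 100 seeded charts per noise condition (the
acceptance script's `--n-charts` controls this); null-ROC and
parameter-recovery checks use n = 500 and n = 200 cohorts. Warps
interpolate bilinearly and round back to uint8; pixel↔value maps are exact
piecewise-linear interpolation with out-of-band inputs raising rather than
clamping; blob areas below 12 px are ignored as specks; all random draws
flow from explicit `numpy` generators seeded by the caller.

## Known limitations

- Multi-chart pages, crumpled-paper dewarping, and automatic dpi inference
  are out of scope; one frame per scan is assumed.
- Marks in colors other than blue/red (e.g. pencil corrections) and
  medication annotations are invisible to the color masks.
- The date reader assumes the handwriting is segmentable into connected
  components; heavily ligatured writing defeats it (on real charts, date
  reading is expected to be the weakest stage by far).
- Rates below ~100 dpi leave too few pixels per mark for reliable blob
  statistics.
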