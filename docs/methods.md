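# Methods

This note records the models, parameter choices and numerical decisions
behind `inclusionprofiler`, and what the synthetic-plate validation does and
does not demonstrate about real microscopy data.

## The measurement problem

A screen of an aggregation-prone fluorescent reporter asks, per well: *what
fraction of transfected cells contain inclusions?* The readout chain is
image → illumination-corrected image → segmented transfected cells →
per-cell feature vector (cytoprofile) → phenotype call → per-well
percentage. Each stage has failure modes (vignetting masquerading as dose
response, dim cells lost at thresholding, texture features confounded by
size), so the package pairs the chain with a generative model of its own
inputs whose ground truth is exact.

## Synthetic scenes (simgen)

Cells are ellipses (aspect ratio U(0.7, 1), random orientation) placed by
rejection sampling so that masks are disjoint and clear of the field border;
placement failure above a density limit raises rather than silently
overlapping. Per-cell diffuse GFP is lognormal(μ=8, σ=0.35) in camera units
(median ≈ 3000 counts over a 100-count background offset), emulating the
wide expression range of transient transfection. Inclusions are rendered as
1–3 Gaussian puncta (FWHM 6 ± 1 px) clipped to the cell mask, with peak
amplitude set so that peak / diffuse equals the contrast parameter
(default 5) exactly in a noise-free, bias-free render — this makes the
punctum the only feature distinguishing the two phenotypes, so classifier
performance measures feature quality, not a rendering shortcut. Nuclei
(13 ± 1.5 px) are drawn concentrically on the nuclear channel.

The default cell equivalent-diameter distribution (31 ± 5 px, truncated to
20–46 px) sits inside the 17–50 px analysis gate; the original imaging
parameters (magnification-calibrated cell sizes, densities) are not public,
so these defaults are chosen as a realistic operating point for ~10×
imaging of adherent neuron-like cells, not as a morphological model of any
line. Illumination bias is a multiplicative radial vignette
(1 − 0.3·(r/r_max)², normalized to max 1); camera noise is Poisson shot
noise (gain 0.5) plus Gaussian read noise (sd 10), then rounding and
saturation at 16 bits. A plate derives one sub-seed per (well, field) from
the plate seed via `SeedSequence` spawn keys: identical seeds give
bit-identical plates, different fields are independent.

Checkerboards: monotherapy effects follow Hill curves
E(d) = E_max·d^h/(d^h + EC50^h) (defaults: E_max 75 at EC50 0.1 µM for the
CuATSM-like agent, E_max 65 at EC50 2.5 µM for the ebselen-like agent, h =
1.5, dose series twofold up to 0.5 µM and 10 µM with zero-dose margins).
The combination surface is max(E_a, E_b) plus an injectable per-pair
synergy offset (margins forced to zero), so the zero-offset surface is an
exact fixed point of the HSA reference. Observed grids are
baseline·(100 − E)/100 plus Gaussian noise (default sd 2 points, 3
replicates), with the no-drug cell equal to the baseline prevalence
(default 27.7%). Live-cell counts are Poisson draws around deterministic
exponential mean curves n₀·e^(−rate·t).

What the simulator does **not** emulate: real cell morphology and contact,
focus drift, debris and autofluorescence, expression-dependent phenotype
coupling, segmentation-relevant subcellular structure beyond puncta, or
plate-edge effects. Passing the validation battery therefore shows the
*chain* is correct and self-consistent under controlled imaging physics; it
does not certify accuracy on any particular real dataset.

## Illumination correction (illumcorr)

The illumination function of a session is the heavily smoothed pixelwise
aggregate of all fields of a channel. Two choices deviate from the most
naive reading of "smooth the mean with a 500-pixel Gaussian":

* **Median, not mean, as the default aggregate.** Cells are sparse and
  bright; the mean of a set of fields carries an average-cell-signal term of
  the same order as the background, which contaminates the surface (measured:
  Pearson r vs the true bias drops from 0.996 to 0.97, and the idempotence
  property below fails outright). The pixelwise median ignores the sparse
  bright minority and tracks background illumination. The mean remains
  available (`statistic="mean"`). At least ~10 fields are needed for the
  median to reject cell leakage.
* **Fixed-point refinement, not a single smoothing pass.** One Gaussian pass
  G∗A attenuates the very trend it should capture (G∗G ≠ G), leaving most of
  the vignette in the corrected images. The surface is instead iterated to
  the smoothing operator's low-pass fixed point, S ← S + G∗(A − S)
  (15 iterations), after which re-estimating on a corrected set yields a
  near-flat function (~2% of the original spatial sd). The smoothing scale
  (default 500 px) is read as a FWHM, σ = scale/2.355, since the source
  convention does not define sigma-vs-width; both are configurable.

Correction is subtractive with a min-preserving offset:
out = clamp(I − S + min S, 0). Subtraction of a multiplicative bias is a
first-order approximation; at this smoothing scale the residual is small
relative to cell/background contrast, and the offset preserves mean
brightness so dim fields are not nulled. Divisive correction is deliberately
out of scope.

## Segmentation (segment)

Foreground thresholds are robust background statistics — median +
6·1.4826·MAD of the lightly smoothed image — rather than Otsu: fluorescence
fields are background-dominated with a foreground spanning over a decade
(dim diffuse cells to bright puncta), and Otsu's threshold drifts into the
foreground, dropping dim cells (log-space Otsu remains as a fallback for
images without a background plateau). Nuclei are separated by seeded
watershed on the distance transform (peak separation 7 px, minimum area
30 px²). Cells grow from nuclear seeds by watershed on inverted GFP
intensity inside the GFP foreground; nuclei of untransfected cells fall
outside the foreground and seed nothing. Without a nuclear channel,
components split by a distance-transform watershed (GFP-only mode, used for
live-cell counting).

The 17–50 "pixel units" gate is applied to the equivalent diameter of the
final mask (the source convention for that phrase is a typical object
diameter); it is a hard contract — no retained object violates it.
Border-touching objects are discarded to avoid truncated cytoprofiles,
matching non-overlapping tile scans. Coordinates are 0-based with
x = column, y = row; bounding boxes half-open. Focus QC scores
var(∇²I)/var(I) (0 for a constant image, strictly lower under blur); it
reports rather than drops by default, since the original procedure excluded
out-of-focus fields manually.

## Cytoprofiles (cytoprofile)

Five families, all computed on masked pixels only, masks under 9 px
rejected:

* **Intensity**: mean, integrated, sd, max, min, median.
* **Shape**: area, perimeter, eccentricity, form factor 4πA/P², solidity,
  equivalent diameter.
* **Texture**: the 13 classical Haralick statistics of a gray-level
  co-occurrence matrix at offsets 3 and 8 px, summed over the four principal
  directions and symmetrized — so features are invariant under 90°
  rotations by construction. The GLCM is mask-aware (only pixel pairs both
  inside the mask are counted), which off-the-shelf rectangular-window
  implementations cannot do; intensities are quantized to 32 levels between
  the cell's min and max, making texture invariant to intensity scaling.
  Degenerate guards: correlation 0 when a marginal sd is 0, information
  measures 0 when marginal entropy is 0.
* **Granularity**: 16-element granulometry — the fraction of
  background-subtracted intensity (background = cell minimum) removed by
  grayscale openings of increasing size. Structuring elements are squares
  of half-width 1..16: separable min/max filters make the spectrum O(area)
  per size instead of O(area·SE area) for disks, and nesting guarantees a
  nonnegative spectrum summing to ≤ 1. Puncta concentrate removed intensity
  at the first few sizes, making the small-scale elements the single most
  discriminative family.
* **Radial distribution**: 4 concentric bins of normalized
  distance-to-edge; per bin the intensity fraction (sums to 1), the
  area-normalized mean fraction, and the coefficient of variation across 8
  angular wedges.

Features are z-scored per batch (plate); zero-variance features are dropped
with a warning. The per-feature mean/sd are retained and **must** be applied
(`apply_normalization`) when scoring cells outside the training batch:
re-normalizing a plate whose class mix differs from the training pool (e.g.
a 0.8%-prevalence plate against a balanced pool) shifts the feature space
and was measured to inflate the false-positive rate by ~0.8 points —
fatal at a sub-1% readout. A robust (median/MAD) normalization variant was
considered and left out: plain z-scores are the simplest defensible reading
and the classifier is insensitive to the difference on separable data.

## Classification and the review protocol (inclusionclass)

A 100-tree random forest (sqrt features per split, fixed seed,
out-of-bag accuracy reported) on normalized profiles. The decision
threshold on the inclusion-class probability is 0.5 with ties resolved to
*no_inclusion* — conservative for a phenotype whose prevalence is the
readout. Scoring validates the fit-time feature schema and refuses
mismatches.

The training pool is built the way a reviewer would build it: cells are
segmented by the pipeline and then labeled (in tests and validation, by IoU
≥ 0.5 matching against simulator truth — the automated stand-in for a human
labeling segmented thumbnails). Training on ground-truth masks instead
creates a domain shift between training and scoring distributions and was
measured to cost ~0.8 points of false-positive rate at the wild-type
operating point.

The review protocol mirrors the accuracy-assessment procedure: for growing
training sizes, draw `batch` = 100 cells *predicted* as each bin, score
them against the oracle (a precision-like per-bin accuracy — the quoted
procedure counts mistakes among requested cells of a bin), repeat 3 times,
and stop at the first size whose mean inclusion-bin accuracy reaches the
0.97 plateau criterion. Whether the original accuracy figures are per-bin
precision or per-class recall is ambiguous; both are available (the
held-out per-class accuracies are what the validation battery reports), and
the protocol's stopping rule uses the per-bin form.

A Rogan–Gladen-style corrected estimator,
(p̂ + specificity − 1)/(sensitivity + specificity − 1), is provided for
recovering true prevalence under known misclassification rates.

## Synergy (synergy)

Each replicate grid is normalized to its **own** no-drug control
(×100/control) before any averaging — averaging first and normalizing once
gives a different, control-weighted answer. Effects are
E = 100 − %control, so positive values mean reduced inclusion formation;
values above control (E < 0, worsening) are retained, not clipped, so
antagonism stays visible. The HSA reference is R(a,b) = max(E(a,0),
E(0,b)); S = E − R is computed per replicate and averaged, with the
replicate sd reported. Monotherapy margins are their own reference and
score exactly 0 by definition — including when a monotherapy worsens the
readout, where max(E, 0) would otherwise leak a negative "synergy" onto the
margin. Calls are strict: S > 10 synergistic, S < −10 antagonistic, 10
itself neutral. Scores are raw differences; no surface smoothing or model
fitting is applied before differencing, which can diverge from tools that
smooth first. Loewe and Bliss references are out of scope (the HSA model is
the appropriate reference when both agents act on the same pathway).

## Survival and dose response (viability)

Relative survival divides each series by its own t₀ count and then by the
matched control series at the same timepoint (same-treatment control by
default; the alternative normalization is a flag). AUC is the trapezoid
rule on the raw timepoints — exact for piecewise-linear curves, no
resampling. Significance testing is deliberately exported (per-replicate
AUC tables) rather than reimplemented.

The 4PL fit uses least squares on log₁₀ concentration with quantile-derived
starting values; zero doses enter at (min nonzero dose)/100 on the log
axis, the standard convention for log-inhibitor fits. The hill sign follows
the observed response direction, so rising curves fit with a flipped slope.
Non-convergence returns the seeded parameters with a warning and a flag
instead of raising; an IC50 outside the dosed range is flagged
extrapolated.

## Validation battery sizes

The acceptance script uses 20 fields (~800 cells) for segmentation recall,
a ~2400-cell pool (60 fields at balanced prevalence) for classifier
training/evaluation, three 15-field plates for the review-protocol sample
efficiency, and ~8000 / ~3200 cells for the prevalence-recovery runs at the
0.8% and 27.7% operating points — the 0.8% run needs the largest plate
because the binomial sampling error of the realized prevalence
(≈ 0.1 points at n = 8000) must sit well inside the ±0.3-point target
band. These sizes were chosen so each number is statistically meaningful on
one CPU in minutes; the test suite runs reduced versions of the same
checks.
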