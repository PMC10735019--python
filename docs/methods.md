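# Methods

This note records the scientific and numerical choices behind
`trackqc`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Segmentation

Pits are darker than the background, so the foreground is every pixel
with grey level ≤ the threshold. The default threshold is 120 (a repo
constant — the acquisition software's value is not recoverable), with
an Otsu automatic mode (`threshold="auto"`) for images whose background
level differs. Components are maximal 8-connected sets, labelled 1..n
in raster order of each component's first pixel so labelings are
deterministic.

Overlapping tracks are split by a watershed on the Euclidean distance
transform. Markers are the connected plateaus of regional maxima found
with a (2s+1)² maximum filter, s = 3 px minimum peak separation by
default. Using plateau *regions* rather than individual plateau pixels
means a convex object — including a flat ridge such as a thin bar —
carries exactly one marker and is never split, while a dumbbell of two
overlapping discs carries two. Splitting partitions the original
component's pixels and can never merge components.

No minimum object size is applied by default: isolated dark pixels are
themselves a symptom of poor illumination and feed the quality-control
features.

## Descriptors

* **Area** — pixel count of the component. Interior holes are *not*
  counted; `filled=True` switches to the filled convention (both
  conventions exist in commercial analysers and the choice is
  documented rather than assumed).
* **Diameter** — the longest segment joining two border-pixel centres
  that passes within half a pixel of the intensity-unweighted centroid.
  A single pixel has diameter 0. If no border pair passes near the
  centroid (strongly non-convex objects), the maximum border-to-border
  distance is used as a fallback.
* **Aspect ratio** — √(λ₁/λ₂) of the second-central-moment matrix with
  1/12 added to each diagonal term (the variance of a unit square), so
  one-pixel-wide objects are finite and a uniform a×b rectangle returns
  exactly a/b.
* **Roundness** — P²/(4πA). The perimeter estimator is the weighted
  4-neighbourhood chain-code length (`skimage.measure.perimeter`),
  declared once and used consistently: it gives 1.10 for a digital disk
  of radius 8 (the discretization error of the estimator, not a shape
  property) and 20.0 for a 3×9 rectangle. Sub-pixel objects aside, any
  consistent estimator only rescales the roundness distribution; what
  matters for classification is the declared, frozen convention.
* **Heterogeneity** — fraction of pixels with |I − mean| > 0.10·mean.
  An all-zero object returns 0 (degenerate; cannot occur for dark pits
  on a bright background after thresholding).
* **Clumpiness** — heterogeneity after one erosion with a full 3×3
  structuring element ("border pixels" = the one-pixel rim). Objects
  that erode to nothing return 0.

Summary statistics per image: mean, median, interquartile distance
(p75 − p25), population standard deviation, 5th and 90th percentile,
all with linear interpolation between closest ranks. 6 statistics × 6
descriptors = 36 features, plus the track count.

The pixel→μm² factor is (211/1280)·(158/962) ≈ 0.02707 μm²/px, derived
from the stated field of view. (A 30–40 px pit is then 0.81–1.08 μm²;
reported figures of 0.86–1.15 μm² for the same pixel range imply a
slightly different conversion whose origin is unclear — the field-size
value is used here.)

## Preprocessing and projection

The two 5th-percentile columns for roundness and clumpiness are dropped
(their first histogram bin holds >5% of objects in every image, pinning
the percentile). Balancing undersamples the majority class to
2·min(class counts), seeded. Splitting is stratified 0.64/0.16/0.20
(a 20% held-out test set, then 20% of the remainder for validation).

PCA standardizes features on the training statistics (zero-variance
guard: unit scale), i.e. diagonalizes the feature correlation matrix;
whether to standardize was an open design point and the correlation
form was chosen because the feature units differ by orders of
magnitude. Raw-covariance PCA is available via `standardize=False`.
The smallest k with cumulative explained variance ≥ 0.999 is retained.

## Classifiers

**SVM** — RBF kernel; randomized search over C ∈ [0.1, 30] and
γ ∈ (0, 0.3] (50 candidates, 5-fold CV by default; the historically
reported optimum C = 16.5, γ = 0.09 lies inside this box). The model is
refit on all training data; out-of-fold decision values are retained so
cross-validated confusion matrices and prediction histograms can be
reported. The acceptance probability is the plain logistic of the
signed decision value — a monotone squashing, not a calibration.

**Neural network** — 3 hidden layers × 150 rectifier units, dropout
0.24 after hidden layers 1 and 2, L2 coefficient 10⁻⁴ (unreported
upstream; exposed in config), single logistic output trained with
binary cross-entropy, Adam at 1.5·10⁻³, batch 16, ≤1000 epochs.
Validation-loss callbacks: multiply the learning rate by 0.18 when the
loss fails to improve by 0.01 for 12 consecutive epochs; stop after 24
and restore the best weights. The published configuration table pairs a
sigmoid output with a sparse-categorical loss, which is internally
inconsistent; the logistic/binary-cross-entropy head matches prediction
histograms on [0, 1] and a 0.76-type threshold, and a two-unit softmax
head is available behind `output="softmax"` for comparison. The network
is implemented directly on numpy with explicit seeding, so training is
bit-reproducible run to run.

**Operating point** — predictions are Accepted iff p > threshold
(strict, so threshold 1.0 rejects everything). The operating threshold
is the smallest threshold whose precision reaches the 97% target;
since recall is non-increasing in the threshold this maximizes recall
subject to the constraint. Ties in scores are grouped; candidate
thresholds are the distinct score values plus an accept-everything
sentinel. `project_confusion` rounds to the nearest integer, ties away
from zero (tp = round(r·n₊), fp = round(tp·(1−p)/p)).

## Synthetic generator

The generator's defaults encode the study conditions:

* **Decay channels**: α at 1.777 MeV + ⁷Li at 1.013 MeV with intensity
  6.3%, α at 1.471 MeV + ⁷Li at 0.839 MeV with 93.7%. One fragment per
  capture (equal odds α/Li) reaches the detector — the two are emitted
  back-to-back, so only one can enter it.
* **Energy→area**: piecewise-linear through (0.5 MeV, 41 px),
  (1.0 MeV, 33 px), (1.47 MeV, 25 px) — larger pits at lower energy,
  where the Bragg peak concentrates damage near the surface; clamped
  outside the anchors. Implanted-standard mode uses the bimodal anchors
  12 px (α) and 55 px (Li).
* **Depth spread**: emission depth uniform within the fragment's range;
  with a power-law range–energy relation R ∝ E^1.8 the residual surface
  energy is E₀·u^(1/1.8), truncated at a 0.5 MeV registration threshold
  (the calibration's lower anchor). This is a deliberate simplification
  — no stopping-power transport is simulated — but it reproduces the
  broad unimodal area distribution with mode in 30–40 px and a steeper
  fall towards large areas.
* **Per-pit dispersion**: log-normal area scatter with relative s.d.
  0.18; aspect 1 + |N(0, 0.12)| capped at 1.6; orientation uniform.
* **Rendering**: dark elliptical core (grey ≈ 40) with a linear radial
  intensity ramp of 1–2 px centred on the nominal ellipse boundary, on
  a background of grey 200 with additive N(0, 8) sensor noise. With the
  default threshold 120 the measured boundary falls at the ramp
  midpoint, so measured areas track the nominal πab within a few
  percent, and the rim carries the grey-level gradient that makes
  heterogeneity bimodal while erosion (clumpiness) removes it.
* **Corruption**: a lamp offset adds ±offset·120 grey levels (over-
  lighting clips the rim above threshold and shrinks pits; under-
  lighting drags the background noise tail below threshold, flooding
  the frame with few-pixel objects). Defocus is a Gaussian blur of the
  stated sigma plus re-injected sensor noise (3·min(σ,2) grey levels)
  that cuts ragged outlines at the threshold, inflating the roundness
  and aspect tails. Zero-magnitude corruption is the pixel-for-pixel
  identity.
* **Adequate band**: |light offset| ≤ 0.15 and defocus σ ≤ 0.8 px —
  repo constants defining the Accepted label. Degraded draws sample
  |offset| ∈ [0.35, 0.7] or σ ∈ [1.2, 2.2]. There is no quantitative
  mapping from lamp units or lens distance to these magnitudes; they
  are defined so that degraded frames show the documented qualitative
  distortions at clearly measurable size.
* **Track density**: Poisson, mean 200 per full 1280×962 frame,
  scaled with frame area.

All randomness flows from one seed through `numpy` seed sequences;
fixed seeds give bit-identical datasets.

**What the generator does not emulate.** Tissue texture, cell contours,
detector scratches and folds; correlated (optical) noise — sensor noise
is i.i.d. per pixel, which on dark cores (grey ≈ 40, 10% band = ±4)
keeps many within-core pixels outside the heterogeneity band, so
synthetic clumpiness sits higher than the near-zero values typical of
real adequate tracks; oblique incidence (aspect spread is statistical,
not geometric); and any light–focus interaction. Consequently, passing
end-to-end tests demonstrates that the pipeline separates the encoded
corruption modes — not that a model trained on synthetic frames
transfers to real micrographs.

## Problem sizes and numerical choices

Tests and the acceptance script run the synthetic study on 320×416 px
frames (track density scaled accordingly, ~25 tracks/frame) with
120–300 images — the package's chosen desk-scale study sizes; the
generator's default frame remains full size. Percentile interpolation,
erosion structuring element, perimeter estimator, the strict-inequality
decision rule and the tie-away-from-zero rounding are all frozen and
tested against brute-force oracles. Degenerate inputs: empty masks
label to zero objects; images where nothing segments are reported as
not classifiable rather than scored; zero-denominator metrics return an
undefined marker (`None`), never a number.

## Known limitations

* The historical ~22k-image feature table is not redistributed here;
  the reproduction protocol for it ships in the acceptance suite and
  activates when the CSV is placed at `data/s1_parameter_dataset.csv`.
* Synthetic classes are separable by construction; reported synthetic
  accuracies/AUCs are upper bounds relative to expert-labelled data.
* The clumpiness fidelity gap described above.
* The SVM probability is an uncalibrated logistic squashing; only the
  ordering (ROC/PR, threshold selection) should be interpreted.
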