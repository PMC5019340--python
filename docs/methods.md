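# Methods

This note documents the models, algorithms and design choices behind
`desilasso`: what is computed, under which assumptions, and what the
synthetic experiments do and do not demonstrate.

## Data model and preprocessing

A sample is a rectangular grid of pixels (default spacing 200 µm), each
holding one negative-ion-mode spectrum on a shared mass axis; the default
axis has 13,320 channels spanning m/z 90–1,200 (~0.0833 m/z per channel).
Pixels without a spectrum are background (glass slide).  Annotations assign
each pixel one of five labels — cancer, glands, stroma, excluded
(lymphocytes / inflammation / necrosis) or background — and may carry a
region-level percent composition, the form in which pathologists describe
mixed-histology regions.

Preprocessing averages non-overlapping bins of six channels (arithmetic
mean; a trailing partial bin is averaged over its actual members), reducing
each spectrum to 2,220 features labeled by bin-center m/z.  Binning is the
only registration mechanism: no smoothing, peak picking or alignment is
applied, so small mass-calibration differences between spectra are absorbed
by the ~0.5 m/z bin width.  Feature labels are displayed to one decimal,
which places them on the half-unit m/z grid used in the packaged reference
weight table.  TIC (total-ion-current) normalization is available but off
by default; the default pipeline feeds raw binned intensities to the
classifier, which standardizes features internally.  When no annotation
mask exists, a fallback flags pixels with TIC below 5% of the sample median
as background; the threshold is a package choice (the exclusion of glass
pixels is qualitative in origin).

Only pixels labeled cancer / glands / stroma enter training and testing;
background and excluded pixels are dropped.

## The classifier

The core model is multinomial logistic regression with an L1 penalty on
standardized features:

    minimize over (W, b):  (1/n) Σᵢ [logsumexp(zᵢ) − z_{i,yᵢ}] + λ Σ|W|,
    zᵢ = W' (xᵢ − μ)/σ + b

Weights are reported on the standardized scale — dimensionless and
comparable across m/z — with (μ, σ) stored on the results object so users
can invert the scaling.  The penalty is plain, unweighted L1 across all
classes and features; intercepts are unpenalized and centered to sum to
zero (the softmax is invariant to a constant shift, and centering makes the
reported intercepts unique).

Sign semantics: a positive weight marks an ion whose abundance
characterizes the class; a negative weight marks one whose low abundance or
absence does.  The weight table lists only features with at least one
nonzero class weight.

### Solver

The objective is solved by FISTA (accelerated proximal gradient with
backtracking line search and adaptive restart) on a working set of
features: the warm-start support plus every feature violating the KKT bound
|∂NLL/∂w| ≥ λ at the warm start.  After the working set converges, a full
gradient sweep adds any violators and the solve repeats, so the returned
solution satisfies the KKT conditions over *all* features to the requested
tolerance (default 1e-7 for final fits).  Standardization is applied
implicitly inside the matrix products, so the raw feature matrix is never
copied.  An earlier design used the sequential strong rule
(|g| ≥ 2λ_t − λ_{t−1}); on the coarse penalty grids this package favors the
rule degenerates (the threshold can go negative, admitting every feature),
so the plain KKT-bound working set is used instead.

λ_max — the smallest penalty with an all-zero solution — is computed in
closed form from the gradient at the intercept-only fit.  Paths are fitted
on a log-spaced grid from λ_max downward with warm starts.  Numerical
dust (|w| < 1e-10) is zeroed so that reported support sizes are exact at
penalty saturation.

Solver correctness is established in two independent ways: (i) on small
random problems the objective at the returned solution matches a generic
convex optimizer (L-BFGS-B on the split w = w⁺ − w⁻) to 1e-6 relative, and
(ii) the KKT residual is checked explicitly at every returned solution.
The oracle shares no code with the solver.

### Cross-validation

The penalty is chosen by leave-one-patient-out CV: folds are patients, the
fold's model is fitted on all other patients' pixels, and misclassified
held-out pixels are totalled across folds per λ.  The chosen λ minimizes
total pixel misclassifications, with ties broken toward the larger (more
parsimonious) penalty; a per-patient-mean error curve is also exposed for
users who prefer patient-weighted selection.  The final model is refit on
all training pixels at the chosen λ.  For large cohorts the CV search can
subsample a fixed number of pixels per patient (seeded); the refit always
uses every pixel.  CV-path fits run at a relaxed tolerance (1e-5, iteration
cap 2000 per solve) since they only rank penalties; final fits are solved
tight and uncapped.

Prediction is per pixel: softmax probabilities, argmax class, ties broken
by class order (cancer < glands < stroma) for determinism.

## Customized training

For a mixed-histology test sample, test pixels are clustered jointly with
the training pool — k-means with G centroids (default G = 3, one per tissue
class) on the feature-wise standardized union, k-means++ initialization, 10
restarts, fixed seed.  Each cluster containing test pixels gets its own
lasso fitted to the training pixels assigned to that cluster, with its own
patient-grouped CV over the patients present; its test pixels are predicted
by that local model.  A cluster whose local training set has fewer than 30
pixels of any class (configurable) falls back to the global model, which
prevents degenerate one- or two-class fits; a single-patient cluster, where
grouped CV is impossible, reuses the global penalty on the local data.
With G = 1 the procedure reduces exactly — same code path, same model — to
the global classifier.  Clustering is per test sample, matching the
procedure's description as building a customized training set *for each
test sample*.

## Synthetic cohort generator

The generator exists so that every pipeline stage is testable with known
ground truth.  It emulates, at the level the classifier sees:

* **Class lipid profiles.**  Gaussian peaks (default σ = 0.15 m/z, ~2
  channels, so each named lipid lands in a predictable 0.5-m/z bin) at the
  m/z of the ions that dominate negative-mode pancreatic spectra: glands
  rich in free fatty acids (palmitic 255.3, oleic 281.2, arachidonic 303.3)
  and their dimers (537.0, 563.0); cancer rich in polyunsaturated FAs
  (303.3, adrenic 331.2) and PC/PG/PI species (792.4, 794.4, 773.6, 885.6);
  stroma sharing the FA ions with traces of the glands dimers, with weak PS
  markers (788.8, 816.5) and a total-abundance scale of 0.35 versus 1.0
  (glands) and 0.9 (cancer) — stroma's low ion yield is what makes it the
  hardest class, and the default profiles were calibrated so the synthetic
  difficulty ordering matches that regime.
* **Noise.**  Per-pixel log-normal intensity variation (mean 1, default
  CV 0.6), an additive baseline (default 2 counts/channel expected), and
  Poisson shot noise on expected counts; peak amplitude defaults put
  signature peaks at tens of counts.
* **Patient effects.**  Per-patient log-normal multipliers (default
  sd 0.35) applied independently to each profile peak — the between-patient
  variation that makes leave-one-patient-out CV the honest error estimate.
* **Mixed histology.**  A region with composition c draws each pixel's
  truth label from c (cell-level mixing at 200-µm pixels) and blends each
  pixel's expected spectrum as (1−β)·T_label + β·T_mix(c) with β = 0.3, a
  partial-volume effect.
* **Batch shifts.**  Optional additive contaminant peaks shared by all
  spectra of a sample (used to emulate acquisition-batch structure).

Everything is driven by a single seed through spawned generator streams, so
cohorts are bit-reproducible.  The generator does **not** model
desorption/ionization physics, isotope patterns, adducts, chemical noise
correlations, or spatial texture within regions; passing synthetic tests
therefore demonstrates the statistical machinery (binning, sparse
classification, grouped CV, cluster-local adaptation, margin logic) under
the assumed data model, not instrument-level robustness on real tissue.

## Evaluation conventions

Agreement is pixel-level: per-class agreement is diag/rowsum of the
confusion matrix, overall agreement is trace/n.  Uncertainty uses the
binomial standard error 100·√(p(1−p)/n).  Display follows the field's
reporting convention — agreements to 0.1 percentage point, SEs to 0.01 —
and the SE is evaluated at the display-rounded agreement, which is the
convention that reproduces the packaged reference tables cell for cell;
full-precision values are kept internally.  Class merging (e.g. glands and
stroma into one "normal" class) sums matrix cells and preserves the pixel
total.

Sample-level rules: the majority rule calls a sample "cancer" iff strictly
more than 50% of its predicted pixels are cancer.  Percent-composition
comparison checks |predicted % cancer − pathology % cancer| against a
tolerance (default 10 percentage points) per region.  Margin flagging marks
a margin positive when its cancer-pixel percentage exceeds a threshold
(default 1%, deliberately below the method's ~2% pixel error floor and
configurable); a case is positive iff any of its margins is.

## Study-scale experiments

Two experiments wire everything together (`desilasso.experiments`); both
are run by the test suite and the reproduction script.

**Held-out agreement.**  25 training patients plus 3 held-out patients, one
45×45 sample each (2,025 pixels/patient) with a glands-dominated layout
(60/30/10 glands/cancer/stroma), default noise.  The CV search uses a
12-point λ grid down to 10⁻³·λ_max on a seeded subsample of 100 pixels per
patient; the final refit uses all ~50k pixels (tolerance 1e-5, iteration
cap 1500 — per-pixel predictions saturate long before the tightest KKT
tolerance is reached).  Samples are generated and
binned one at a time so the raw 13,320-channel spectra of the cohort are
never simultaneously in memory.  Expected regime: glands and cancer in the
high 90s, stroma in the 80s–low 90s and always the hardest class.

**Customized vs global on mixed samples.**  8 training patients
(equal-thirds banded layouts, 20×20), of which 2 carry an additive batch
shift — spurious peaks at m/z 303.3 and 331.2 (the polyunsaturated-FA
markers), amplitude drawn uniformly from 15–30 counts — and 20 test
samples, each a fresh patient with a single 16×16 region of 20% tumor cells
in 80% stroma carrying the same kind of shift.  Clustering pairs shifted
test stroma with the shifted training patients' stroma, giving the local
model labeled counterexamples for the contaminant, while the global model
remains a single cross-batch compromise.  The recorded outcome is the mean
absolute error of the predicted percent-cancer composition for both
methods.  Known limitation: when the batch shift is unique to the test
sample (no shifted patients in training), *neither* model has
counterexamples and customized training does not improve on the global
model — both linear models extrapolate identically along the contaminant
direction; cohort-level batch structure is what the method exploits.  In
this synthetic regime the global model is itself fairly robust, so the
improvement is consistent but modest in magnitude.

## Numerical and degenerate-input conventions

* Objective tolerance: KKT residual ≤ 1e-7 (final fits) / 1e-5 (CV path);
  probabilities sum to 1 to 1e-12 by construction of the softmax.
* At λ ≥ λ_max the fit is exactly the intercept-only model; its predictions
  are the training class frequencies.
* Single-class training data, non-finite features, mismatched grid/mask
  shapes, empty confusion matrices, zero-area regions and compositions not
  summing to 1 (tolerance 1e-9) are rejected with specific errors; a
  pathology class with zero pixels is skipped with a warning in agreement
  reports; an all-zero pixel is left unchanged and flagged by TIC
  normalization.
* k-means clustering runs on a float32 copy of the standardized union for
  speed; assignments are deterministic given the seed.
* Text I/O prints intensities with 17 significant digits, so float64
  spectra round-trip bit-identically.

## Limitations

Beyond the generator's scope (above): the pipeline assumes an
already-rectangular pixel grid (instrument scan-line geometry and
aspect-ratio rescaling are out of scope); profile-mode peak picking, vendor
raw-file conversion, lock-mass recalibration and deisotoping are not
implemented; survival analysis of margin-status groups is out of scope.
Whether intensities should be TIC-normalized before fitting is data-
dependent; the package defaults to raw binned intensities with in-solver
standardization and exposes normalization as an option.
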