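# Methods

## Problem setting

A binary image classifier can separate its classes using *acquisition-
dependent attributes* (ADAs) — global image properties such as contrast and
sharpness set by the detector, protocol, or vendor post-processing — whenever
those attributes correlate with the labels, e.g. when positives and negatives
were collected at different sites. This package operationalizes the detection
of such shortcuts: train a classifier that can *only* see one ADA, prove that
it sees nothing else, and then use its discriminative performance on a
candidate dataset as a measurement of that ADA's label correlation.

## ADA operators

Contrast and sharpness are each modeled by the canonical single-parameter
operator of that attribute family:

* contrast: global power-law mapping `out = 255 (p/255)^γ`, `γ > 0`, computed
  in real arithmetic and quantized at the end. Monotone in intensity, fixes 0
  and 255, `γ = 1` is a bit-exact no-op.
* sharpness: Gaussian blur of scale `σ` pixels (softening) or unsharp mask
  `out = in + a·(in − G(in, σ₀))` with fixed internal `σ₀ = 1` px
  (sharpening). At most one direction per spec; both parameters zero is a
  bit-exact no-op. Blur strictly decreases mean squared gradient magnitude on
  non-constant images; unsharp masking increases it.

These operators were chosen because they are the standard one-parameter
controls for the two attributes, are monotone in magnitude, and are cheap
enough to apply per-image in the exam loop. Injection uses a fixed magnitude
per dataset build; the defaults (γ = 1.3, σ = 1.0 px at 64×64) are strong
enough for ceiling-level detectability while remaining far smaller than
pathology-scale intensity changes. Numerical conventions are pinned for
bit-exact reproducibility: quantization rounds half-away-from-zero; Gaussian
filtering uses reflective boundaries.

## Phantom generator

The synthetic data stand-in emulates the gross structure of a frontal chest
radiograph: one bright body ellipse (default mean 180) on a dark background
(25), two mirrored darker lung ellipses (80), `rib_count` sinusoidal bands
(amplitude 20) across the lung fields, additive clipped Gaussian noise
(SD 5), and per-image anatomy jitter (5% of ellipse axes/centers). Every
image — regardless of label — additionally receives a baseline gamma draw
from (0.95, 1.05) and a baseline blur draw from (0, 0.5) px. The baseline
jitter is the load-bearing design element: it forces detectives to learn the
injected *shift* in the attribute rather than an absolute value, mirroring
natural acquisition variation. The jitter ranges are free parameters of the
phantom; they were set to a modest within-site spread, deliberately smaller
than the injected magnitudes, which is the operating regime the framework
presumes (an injected ADA that drowned inside natural variation would not be
certifiable at the τ₂ = 0.01 exam threshold by any scorer).

Labels in the shortcut-free generator are fair coin flips independent of
image content, so class-conditional distributions of any image statistic are
exchangeable — verified by permutation tests in the suite.

What the phantom does **not** model: pathology, projection geometry, Poisson
noise statistics, vendor-specific local (adaptive) post-processing, or
scatter. Consequently, passing tests show the pipeline's logic and
sensitivity under controlled conditions; they do not show that a particular
clinical dataset is shortcut-free, nor calibrate detection power on real
radiographs.

## Detectives

A detective is an ensemble of five members (configurable) trained on
stratified 5-fold train/validation partitions (grouped by patient when
patient IDs exist). Members are logistic scorers over image features, fit by
SGD with a constant learning rate (0.05), L2 penalty (1e-4), at most 80
epochs, and early stopping on validation AUC with patience 10; the best-
validation-AUC weights are kept. Scores are combined by arithmetic mean —
the simplest rule consistent with calibrated member probabilities. Two
feature backends share this head:

* `feature_linear` (default): nine intensity quantiles, mean, SD, and five
  log-scale gradient/Laplacian energy summaries. The shortcut signal is
  global by definition, so global features suffice, and training takes
  seconds on one CPU.
* `conv_features`: three fixed, seeded random 3×3 convolution banks (widths
  8/16/32) with ReLU and 2× average pooling, global mean/std pooling per
  channel. It preserves the receptive-field structure of a small
  convolutional network while keeping training to the logistic head, so the
  certification suite can exercise a convolutional representation without
  GPU-scale cost. The registry accepts plug-in backends.

Training is deterministic given the config seed (member seeds are derived
from it; inference is pure NumPy).

## Certification and scan thresholds

* Exam 1 tolerance τ₁ = 0.07 around 0.5: wide enough to admit the sampling
  noise of a genuinely uninformative scorer at exam sizes of a few hundred
  to a thousand images, narrow enough to reject mild label entanglement.
* Exam 2 tolerance τ₂ = 0.01 from the extremes: the injected-attribute exams
  are expected at ceiling; a detective that cannot reach 0.99/0.01 under its
  own training conditions is not trustworthy as a measurement instrument.
* Scan rule: `shortcut_detected` iff `|AUC − 0.5| > δ` (δ = 0.10) **and**
  the 95% CI excludes 0.5. The effect-size condition prevents large datasets
  from flagging trivially small but statistically significant deviations; the
  CI condition prevents small datasets from flagging noise.

All three thresholds are config-overridable and recorded in every report.
All three exams always run (no short-circuit), so a failing report still
shows the full picture. Deployment refuses uncertified detectives outright.

## AUC and confidence intervals

Point AUC uses the Mann–Whitney midrank formulation (ties count 0.5),
identical to trapezoidal ROC area; it is cross-checked in the test suite
against exhaustive pair enumeration and against scikit-learn. Confidence
intervals use the stratified percentile bootstrap: positives and negatives
resampled independently with replacement (class counts preserved, so no
replicate loses a class), 2000 replicates, 95% level, seeded. Degenerate
cases behave exactly: perfect separation gives [1, 1], total ties give
[0.5, 0.5]. The percentile interval may exclude the point estimate in
pathological tie configurations; results carry a flag for that case.

## Problem sizes

The package's reference study runs at desk scale: 64×64 phantoms, 600-image
training pools, 400-image injected exams, 1000-image shortcut-free exams.
Image size and all counts are configurable up to clinical-preprocessing scale
(224×224). At the default scale the full train-certify cycle completes in a
few seconds per attribute on one CPU.

## Known limitations

* Only two ADA families (contrast, sharpness) are implemented; real vendor
  pipelines include local operators (adaptive histogram equalization, edge
  enhancement with overshoot control) outside this parameterization.
* The scan verdict is per-attribute; a dataset can harbor shortcuts the
  detective set does not cover. A clean scan is evidence of absence only for
  the attributes scanned.
* Injection direction (whether the positive class is made more or less
  contrasty/sharp) is configurable but fixed per build; mixed-direction
  shortcuts would dilute the exam AUCs.
* DICOM ingestion applies the file's own default window attributes when
  present; vendor-specific VOI LUTs are not interpreted.
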