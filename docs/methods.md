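# Methods

This package compares three strategies for making patch-level H&E
classifiers robust to inter-center stain variation — Macenko stain
normalization, random color augmentation, and domain-adversarial (DANN)
training — under a controlled synthetic multi-center cohort.  This note
records the models, the parameter choices, and what the desk-scale
experiments do and do not show.

## Color model

All color reasoning uses the Beer–Lambert transmission model: a pixel
stained with hematoxylin and eosin at concentrations C = (c_H, c_E) has
channel intensity I_c = I_0 exp(−S_c · C), with S the 2×3 matrix of
per-channel absorbance coefficients and I_0 the background intensity.
Conventions, fixed package-wide:

* natural logarithm in the optical-density transform OD = −ln(I/I_0)
  (the log base is a free choice in the transmission model; it rescales S·C
  jointly and cancels in every normalization ratio used here);
* stain rows stored unit-normalized, concentrations carry all magnitude
  (removes the scale ambiguity of the S·C factorization);
* background defaults to 255 per channel;
* intensity 0 clamped to 1 before the logarithm, bounding OD at ln 255.

The model is strictly two-stain; there is no DAB channel.

## Macenko estimation and normalization

Estimation: background pixels (no channel with OD above 0.15) are
discarded; the remaining OD cloud is reduced to the plane of its two
principal directions (SVD of the mean-centered pixels); pixels are
projected into the plane and the stain vectors are read at the 1st and
99th percentile angles of the projected cloud.  The thresholds 0.15 / 1%
are the established defaults for this estimator.  Any negative components
of the extreme-angle vectors are clipped to zero before renormalization.
The row with the larger red absorbance is labeled hematoxylin: H absorbs
red and green and transmits blue, while eosin absorbs mostly green — this
rule orders the canonical reference vectors H ≈ (0.65, 0.70, 0.29),
E ≈ (0.07, 0.99, 0.11) correctly and is robust to the perturbation ranges
used here.

Normalization maps an image into a template's color frame: brightness
standardization (CIELAB L rescaled so its 95th percentile reaches maximum
lightness, leaving at least 5% of pixels white), per-image Macenko
estimation, least-squares deconvolution of per-pixel concentrations
(negatives clipped to zero), channel-wise rescaling to the template's
robust (99th percentile) concentration range, and re-rendering through the
template stain matrix.  The template is a required explicit input —
normalized results are sensitive to it — and is persisted as JSON.

Degenerate inputs: a collinear OD cloud (single stain) or too few tissue
pixels raise an estimation error carrying the pixel count; per-pixel
deconvolution uses the 2×2 normal equations and rejects near-singular
stain matrices (condition number above 1e8).

## Color augmentation

Training-time channel-wise affine perturbation I′_c = a_c I_c + b_c, with
a ~ U(0.9, 1.1) and b ~ U(−10, +10) intensity levels per channel, drawn
fresh for every patch presentation.  The operation can run in RGB
(default), HSV, or the fixed-basis HED deconvolution space; non-RGB
channels are mapped onto a nominal 0–255 scale first so the ranges mean
the same thing everywhere.  The default ranges are deliberately
conservative: wide enough to blur center signatures, narrow enough to keep
tissue H&E-plausible.  When combined with normalization, normalization is
applied offline first and augmentation online second.

## Tissue heatmap and patch extraction

The tissue-likelihood heuristic (channels on the raw 0–255 scale)

    h1 = tanh(2(B−R)/(G+1) + 0.5) + 0.5
    h2 = tanh((640−R−G−B)/300 + 0.5) + 0.5
    h  = 0.5 tanh(h1 h2 − 1.75) + 0.5

scores white glass at ≈0.085, saturated black at ≈0.347 and purple tissue
above 0.65; thresholding at 0.65 gives the eligible patch locations.
Eligibility is decided at the window's center pixel (the simplest reading
of thresholding "positive locations"; a window-mean mode is available).
Sampling is uniform without replacement; if fewer locations are eligible
than requested, sampling tops up with replacement under a warning.  The
magnification of the input raster (nominally 10X) is metadata only; the
computation is resolution-agnostic.

## Domain-adversarial training

A shared convolutional trunk feeds a task head and a domain head; a
gradient reversal layer (identity forward, gradient × −λ backward) sits
between trunk and domain head.  One SGD step realizes

    θ_f ← θ_f − μ (∂L_y/∂θ_f − λ ∂L_d/∂θ_f)
    θ_y ← θ_y − μ ∂L_y/∂θ_y
    θ_d ← θ_d − μ λ ∂L_d/∂θ_d

with L_y, L_d softmax cross-entropies of the task and domain heads.  The
domain head learns at rate μλ, taken literally from the update rules; with
λ = 0 the domain branch is frozen and the trunk + task head trajectory is
bit-identical to the single-head baseline at the same seed (weight
initialization draws for the domain head come from a separate random
stream precisely so this holds).

Defaults: μ = 0.01 (the compact-model value), λ = 1.0 after a warmup of
100 batch iterations with λ = 0 (warmup stabilizes early training; the
operating λ is a free parameter and 1.0 is the neutral choice), plain SGD
(momentum available but off), dropout 0.25, batch size 30 for 3 training
domains.  Batches are exactly domain-balanced (batch_size/n_domains per
domain, minority domains recycled), which the adversarial update requires;
domain identities travel as one-hot vectors.  The positive class is
oversampled with rotated/flipped copies before training to counter class
imbalance.  Early stopping on validation F1 is available but off by
default.  Training aborts on non-finite losses.  Inference uses the task
head only and never reads a domain label.

The layers (convolution via im2col, batch normalization with running
statistics, 2×2 max-pooling, dropout, dense) are implemented directly on
numpy arrays with hand-written backward passes; every backward pass is
verified against finite differences in the test suite, and the saddle-point
update is additionally checked against hand-derived closed-form gradients
on a linear two-head model.

Architecture (compact model): conv(stride 2) → conv →
[conv + batchnorm + maxpool] ×2 → dropout → conv + batchnorm + maxpool →
flatten, with channels (8, 8, 16, 16, 32) on 64×64×3 inputs; the task head
is dense(128) → dense(2) and the domain head dense(64) → dense(n_domains)
behind the reversal layer.  The stride-2 first convolution and the modest
channel counts keep a full grid run tractable on one CPU; the branch point
is after all shared convolutions because color-sensitive units concentrate
in early conv layers — exactly the features the reversed gradient must
reach.  The 128-wide first dense layer of the task branch is the embedding
layer used for feature export.  A deeper trunk is a config change, not a
code change; pretrained backbones are out of scope.

Training a model with domain-only samples (records whose task label is
unusable) is supported at the update level via a task mask but is not
enabled by any default path.

## Hard-negative mining

A task-only bootstrap model is trained on the positives against an equally
sized random subset of candidate negatives; all candidates are scored and
those with predicted positive probability above 0.5 are kept ("high
probability" is not quantified anywhere authoritative; 0.5 is the neutral
threshold and is config-exposed).  An empty mined set falls back to the
top-k scorers under a warning.  The mined set is computed once and reused
unchanged by every strategy combination.

## Synthetic cohort

The generator emulates the statistical structure of a multi-center patch
dataset without any slide downloads:

* **Class signal (morphology only).**  Hematoxylin channel = sum of
  anti-aliased elliptical blobs; negatives draw 3–6 blobs of radius
  2.5–4.0 px, positives 9–15 blobs of radius 1.6–2.6 px (ranges chosen so
  the expected total blob area matches — classes differ in granularity,
  not stained area).  The per-patch hematoxylin mass budget is 140 ·
  (count/8)^0.05 with ±25% uniform jitter: positives carry ~5% more
  hematoxylin on average, far less than the per-patch jitter, so mean
  color is a poor class predictor (a linear probe on mean RGB stays near
  chance) while the blob statistics are easily learnable from pixels.
  Eosin channel = smooth positive stroma texture (coarse Gaussian grid,
  mean 0.35, upsampled), locally attenuated under strong hematoxylin
  (nuclei displace cytoplasm) — which also gives every patch near-pure
  pixels of both stains, the regime in which Macenko estimation is
  well-posed.
* **Center signal (appearance only).**  Centers sit on a one-dimensional
  "staining protocol" axis: a center at protocol coordinate t rotates the
  canonical H/E vectors by t·4° along a fixed (orthant-preserving)
  direction, offsets brightness by t·8 intensity levels, scales channels
  by 1 + t·0.05·g for a fixed gain direction g, and multiplies all stain
  concentrations by 1 − 0.08·t (under-staining for positive t; this
  coordinate saturates at |t| = 2.5, since staining amount differences
  between labs are bounded in a way color casts are not).  Training
  centers span t ∈ [−1, 1] with jitter; Gaussian pixel noise (σ 1–3) is
  drawn per center.  A single consistent axis — rather than isotropic
  random perturbations — mirrors how real protocol differences (stain
  lots, timing, section thickness, scanner profiles) co-vary, and is what
  makes invariance learned across training centers extrapolate.
* **External shift.**  External centers sit at t ≈ 3.75–4.5 on the same
  axis: stain rows rotated 15°+ (≥ 11° from every training row),
  brightness +30, gains up to ±20%, concentrations at 0.80× (the strength
  cap), noise σ 2–4 — a new lab outside the calibration range of the
  training centers, shifted along the axes the training centers already
  vary on.
* **Partitions.**  Train/validation/internal-test share the training
  centers (disjoint draws); external-test comes from disjoint centers.
  Class imbalance defaults to 1:4 positive:negative (milder than severe
  real-world imbalances, chosen for desk-scale statistical power) and task
  labels are assigned independently of center by construction.

What the generator does **not** emulate: real nuclear chromatin texture,
gland architecture, scanner-specific spatial artifacts (stitching,
focus), within-slide stain gradients, or label noise.  Passing tests
therefore show that the pipeline's machinery is correct and that the
adversarial mechanism removes center signatures it was designed to
remove; they do not certify performance on real histopathology.

## Evaluation protocol

F1 (threshold 0.5 by default; a validation-optimized threshold is
available since trained models are not always calibrated) and ROC AUC per
partition; per-method aggregation over 4 random initializations as mean ±
sample (n−1) standard deviation.  Precision/recall zero-division returns
0.  Paired method comparison uses the two-sided Wilcoxon signed-rank test
on per-record probabilities (correctness-indicator pairing available),
zero differences dropped, exact null for ≤ 25 non-zero pairs and the
continuity-corrected normal approximation beyond.  Feature embeddings:
80 sampled records' 128-d task-branch features projected to 2-D by UMAP
(treated as an external routine).  Domain invariance is quantified by a
held-out linear logistic probe on the features and by a k-NN domain-purity
score.

## Desk-scale experiment sizes

The grid runner executes the 2³ strategy grid at sizes chosen for a
single-CPU workstation: ~2,350 patches of 64×64 (3 training centers ×
(350 train + 80 validation + 170 internal test) + 400 external test),
700 SGD iterations of batch 30 per model (about 11 passes over the
oversampled training set — enough for the task loss to plateau; shorter
runs leave both model families visibly underconverged and seed-noisy),
4 seeds.  External-test F1 is read at the validation-optimized threshold,
since under-stained external patches systematically shrink the evidence
scale and miscalibrate a fixed 0.5 cut long before they degrade ranking.
These sizes are the package's defaults for the synthetic study; the
full-scale experiments the design mirrors (tens of thousands of patches,
56 trained models) require the original image archives.

## Known limitations

* The numpy network trains small architectures only; there is no GPU path.
* Macenko estimation assumes two stains with near-pure pixels of each;
  single-stain inputs raise errors rather than guessing.
* HED-space augmentation uses the fixed canonical deconvolution basis, not
  the per-image estimate, decoupling augmentation from normalization.
* The Wilcoxon comparison tests per-record probability differences, not
  case-level decisions; with thousands of records tiny systematic
  differences become "significant", as significance chasing on patch level
  tends to.
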