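# Methods

`nucquant` implements a complete workflow for detecting, counting and
prognostically scoring nuclear IHC biomarker-positive cells (the motivating
marker is ICOS, an immune-checkpoint protein whose DAB-stained nuclei must
be counted per tissue core): semantic segmentation with a U-Net, watershed
post-processing to separate touching nuclei, pixel- and object-level
evaluation including the aggregated Jaccard index, cell-density estimation,
and survival stratification via a time-dependent ROC cutoff with
Kaplan-Meier/log-rank analysis.

## Synthetic data

Clinical IHC cohorts are not redistributable, so the `fixtures` module
generates the inputs every stage consumes.

**Patches.** Nuclei are filled ellipses (semi-axes 6–11 px by default at a
nominal 0.25 µm/px, i.e. 1.5–2.75 µm — deliberately compact so that 64–256 px
patches hold several nuclei) rendered in DAB-brown (RGB ≈ (96, 60, 22), with
±15% per-nucleus shade variation) on a pale counterstain background carrying
low-frequency intensity texture and additive Gaussian pixel noise (σ = 8 grey
levels, clipped to [0, 255]). A configurable fraction of nuclei is placed as
overlapping pairs whose centres sit 1.2–1.7 mean radii apart; the later
label wins contested pixels but the ground truth keeps two instances, which
reproduces the boundary-connected-nuclei failure mode the watershed stage
exists to fix. Distinct objects are kept at least one dilation apart so
"touching" is an explicit property of pairs, never an accident. All
randomness flows from a single integer seed through one
`numpy.random.default_rng`; no global state.

What the generator does *not* emulate: stain co-localisation and
deconvolution ambiguity, out-of-focus blur, tissue folds and artefacts,
chromatin texture inside nuclei, and realistic nucleus shape variation.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted effects, not clinical-grade accuracy on real
slides.

**Cohorts.** Per-patient density is log-normal (median 150 cells/mm²,
log-scale σ = 0.6). Event times are exponential with hazard
`λ₀·exp(β·z)`, where `λ₀ = 0.12/year` and `z` is the standardised
log-density, so `β` reads directly as a log hazard ratio per log-scale SD
of density. Censoring is an independent exponential (0.05/year) truncated
by a 10-year administrative follow-up cap. These rates give roughly
40–60% events within 5 years at moderate effect sizes, a realistic regime
for a stage II–III colon-cancer cohort.

## Segmentation model

The default network is the classic U-Net built from scratch: four
contraction blocks of two 3×3 conv + ReLU layers, 2×2 max-pooling between
blocks, channel width doubling per level from 64, a two-conv bottleneck,
four expansion blocks with 2×2 stride-2 up-convolutions and skip
concatenation, and a 1×1 projection head. The layer walk counts
16 + 2 + 4 + 1 = 23 convolutional layers at depth 4 (`5d + 3` in general);
our census counts up-convolutions and the 1×1 head as convolutional layers.
The binary problem (background vs. positive cell) is emitted as a single
sigmoid logit, mathematically equivalent to a two-class softmax map.

The network, its backward pass and the optimizers are implemented directly
on numpy (im2col matrix multiplication; gradients verified against central
finite differences in the test suite). Pretrained encoders
(EfficientNet-style backbones etc.) are outside this package's scope — the
encoder is a registry (`segnet.ENCODERS`) where alternatives can be
plugged in; keeping the default from-scratch keeps the package free of
downloaded weights. Models of this size train in seconds-to-minutes on one
CPU at the patch sizes the tests use (64 px); the published patch size of
256 px is supported by the same code.

**Losses.** BCE (stable log-sum-exp form), soft-Dice and soft-IoU
(`1 − overlap ratio`, ε = 1e-7), focal (γ = 2, α = 0.25 — the defaults of
its source), and Lovász hinge on the foreground logit (gradient taken with
the sorted-error weights held fixed, the standard practice). Combination
losses are unweighted sums by default (`bce+iou` style), with optional
positive weights.

**Training.** SGD with Nesterov momentum 0.9 or Adam; initial learning
rate 0.002; decoupled weight decay 3e-5 (biases exempt); batch sizes 2–8.
The "dynamic learning rate" is reduce-on-plateau — factor 0.1, patience 5,
monitoring validation soft-Dice by default (the monitored metric is
configurable; the scheduler fires after `patience` consecutive
non-improving epochs, threshold 1e-4). The returned model is the
best-validation checkpoint. Fixed seeds make single-device runs bit
reproducible.

## Post-processing

Probability maps are thresholded at 0.5 (ties to foreground), the exact
Euclidean distance transform of the foreground is computed (image border
counts as background), regional maxima shallower than `h` are suppressed
with the h-extrema transform (morphological reconstruction), and the
watershed floods the negated distance map from the surviving maxima,
restricted to the foreground. `h` is in pixel-distance units with default
6, the value found optimal for ICOS detection; 8-connectivity is used
throughout.

Numerical choices that matter:

* Markers are detected on the distance map **rounded to whole pixels**.
  Rasterized convex blobs frequently carry several near-tied maxima a
  fraction of a pixel apart; rounding fuses them into one plateau and
  prevents spurious splits, while genuine necks (prominence ≥ 1 px) are
  unaffected. The watershed itself floods the unrounded map.
* `h` is applied with a 1e-7 slack so two exactly equal-height peaks —
  whose reconstruction residues equal `h` up to float rounding — both
  survive. Two equal touching discs therefore always split, whatever their
  neck depth; unequal peaks merge when the shallower one's prominence is
  below `h`, the defined behavior of the h-extrema transform.
* A component whose every maximum is suppressed (e.g. `h` above its global
  distance maximum) is kept whole rather than dropped, so foreground is
  conserved: instance pixels always partition the binarized foreground.
* An optional `min_area` filter (default off; 30 px in the reference
  pipeline configuration) removes small instances, the mechanism by which
  post-processing removes speckle false positives.

Raising `h` never increases the instance count (verified as a property
test); `segment` is idempotent on the silhouette of its own output.

## Evaluation

Pixel level: confusion counts, accuracy/sensitivity/specificity, Dice
`2TP/(2TP+FP+FN)`, and pixel-pooled ROC and precision–recall curves with
trapezoidal AUC. Pooling pixels over patches is the default; per-patch
averaging is available (`mode='patch_mean'`) and labelled, since the two
conventions differ. Metrics with empty denominators are reported **absent**
(`None`), never 0 or 1, and excluded from means; the count of such patches
is reported.

Object level: the aggregated Jaccard index follows the established
convention — each ground-truth instance selects the prediction maximising
its Jaccard index, predictions are consumed at most once (claims resolved
in descending best-Jaccard order, ties to the lower prediction id), and
never-matched predictions are penalised in the denominator. The greedy
matching is guarded in the tests by an exhaustive-assignment oracle on maps
with ≤ 4 instances. Object precision/recall use one-to-one greedy IoU
matching with a configurable acceptance threshold (default IoU ≥ 0.5 —
the object-level true-positive criterion must be explicit to be testable).
The threshold sweep re-runs the full post-processing chain per probability
threshold and emits a `threshold, precision, recall` table.

## Density and survival

Density is `detected instances / analysed area`, with area the
analysed-pixel count times `(mpp/1000)²` (mask-aware, so artefact exclusion
reduces the denominator); `mpp` defaults to 0.25 µm/px, the nominal
resolution of 40× scans, and is a documented assumption. Concordance
between predicted and reference densities is the Pearson product-moment
correlation.

The time-dependent ROC at horizon `t` (default 5 years) uses the
cumulative-case/dynamic-control definition with Kaplan-Meier adjustment:
`sens(c) = P(X>c)(1−S_{X>c}(t))/(1−S(t))`,
`spec(c) = P(X≤c)S_{X≤c}(t)/S(t)`, with subgroup and overall survival from
separate KM fits. Candidate cutoffs are the unique observed densities; the
optimal cutoff maximises Youden's J with ties broken toward the lower
cutoff; AUC is trapezoidal over the (FPR, TPR) points traversed in
lexicographic order. A naive variant that drops patients censored before
the horizon is available for comparison (`adjust='none'`). "5-year
survival" is implemented as administrative censoring at the horizon before
the standard two-group log-rank test (lifelines).

## Known limitations

* **Optimal-cutpoint selection bias.** Choosing the density cutoff by
  maximising Youden's J on the same cohort the log-rank test is then run
  on makes the plain log-rank p-value anti-conservative: on
  zero-effect synthetic cohorts (n = 200) the chain rejects at the 0.05
  level in roughly 20–25% of replicates (measured in the test suite),
  not 5%. This is a property of the optimal-cutpoint procedure itself, not
  of the implementation; p-values from this chain should be interpreted as
  descriptive unless the cutoff is prespecified or validated on an
  independent cohort.
* The survival-curve machinery covers two-group comparison only; no Cox
  modelling, competing risks or multivariable adjustment.
* The watershed separates convex, blob-like nuclei; heavily elongated or
  lobulated nuclei would need shape-aware post-processing.
* The from-scratch encoder at tiny widths is appropriate for the clean
  synthetic fixtures; real IHC data would warrant the full-width model and
  richer augmentation, and typically a pretrained encoder.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own defaults for its synthetic-fixture studies:
segmentation runs use 64 px patches, a depth-2/width-8 U-Net, 45/5/20
train/val/test patches and ≤ 25 epochs; watershed separation is measured
on 200 generated touching pairs; survival recovery uses cohorts of n = 200
with 100 replicates at effect β = 1 and 500 at β = 0.
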