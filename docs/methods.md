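# Methods

## The problem and the metric methodology

In multiclass medical-image segmentation the background class is both
enormous (often ≥ 90–95% of pixels) and easy: it is roughly constant
across slices and patients. Any metric computed over all pixels at once —
accuracy, specificity, FPR, even IoU — is therefore dominated by the
background and reports high scores regardless of how badly the small
target structures are segmented. An all-background classifier on a 95%
background image has 95% accuracy and segments nothing.

The methodology here is: replace the global counts TP/TN/FP/FN by
per-class counts TPc/TNc/FPc/FNc (for class c, a pixel is TP if both maps
say c, FN if only the groundtruth does, FP if only the prediction does,
TN otherwise — so the four counts partition the image for every class),
compute every metric per class, and aggregate as an arithmetic mean over
classes, optionally excluding the background. The informative metrics in
this setting are per-class IoU (Jaccard, JI = TP/(TP+FP+FN)), dice
(DSC = 2TP/(2TP+FP+FN) = 2JI/(JI+1)), and precision/recall; specificity,
FPR and ROC/AUC remain implemented as point values but are dominated by
the background TN term and should not be used to judge per-structure
quality.

**Undefined values.** A ratio with a zero denominator (e.g. IoU of a class
absent from both maps) is reported as NaN and excluded from class means —
both numerator and denominator of the mean. Coercing 0/0 to either 0 or 1
would bias averages for absent classes; exclusion is this package's
choice (the convention is genuinely open in the literature).

## The loss family

All losses are "1 − quality" scores in [0, 1] except cross entropy, which
is unbounded above (the package deliberately does not clamp it; a loss
need only be ordered, not bounded, for gradient descent).

* **crossE** — mean over pixels of w(class) · (−log s_true), where s_true
  is the predicted probability of the pixel's true class, clamped below at
  `smoothing_eps` before the log. The weights w implement class balancing:
  w_c ∝ 1/freq_c over the training set, normalised to mean 1, so rare
  classes contribute as much signal as the background. A class with zero
  training pixels is flagged and smoothed as if it had one pixel.
  The noBK analogue of crossE is a zero background weight (the class
  average form does not apply to a per-pixel loss).
* **IoU loss** — 1 − (1/C) Σc TPc/(TPc+FPc+FNc).
* **dice loss** — 1 − (1/C) Σc 2TPc/(2TPc+FPc+FNc).
* **IoUxy** — 1 − (1/C) Σc TPc/(TPc + α·FPc + β·FNc) with α+β = 2,
  α, β ≥ 0 (a Tversky-style index). α=β=1 recovers plain IoU, bit-identically.
  β > α penalises false negatives harder (favours recall), α > β penalises
  false positives (favours precision).
* **noBK variants** — the class average runs over foreground classes only,
  making the loss independent of pixels that are background in both maps.
  Dice/IoU are already class-balanced (each class contributes 1/C whatever
  its size), so inverse-frequency weighting applies to crossE only.

**Soft (differentiable) forms.** The count formulas are stated on
labelmaps; for training they are relaxed with probability-weighted counts
TPc = Σ s·t, FPc = Σ s·(1−t), FNc = Σ (1−s)·t over pixels, where s is the
per-class score and t the one-hot groundtruth. On a one-hot score map the
soft counts equal the integer counts exactly, which is the consistency the
test suite enforces against an independent per-pixel counting oracle. A
smoothing constant ε (default 1e-6) is added to the numerator and
denominator of every per-class ratio so a class absent from a minibatch
contributes ratio 1 (zero loss) instead of 0/0. Gradients are analytic:
d(num)/ds and d(den)/ds are linear in t, and the quotient rule gives
d(loss)/d(scores) in closed form; correctness is verified against central
finite differences (tolerance 1e-4) for all five preset conditions.

**Minibatch aggregation.** Counts are pooled over the whole minibatch
before the per-class ratio is formed (micro-averaging), then averaged over
classes; this stabilises the terms of classes with few pixels per image.

## Synthetic phantoms

The generator emulates abdominal-scan structure at desk scale: each
non-background class is one ellipse ("organ") with jittered radius, aspect
and position, rejection-sampled to avoid overlap, on a dark background;
class intensities are evenly spaced means plus i.i.d. Gaussian noise.
Defaults: 80×80 grid, 5 classes, background fraction 0.95 (the imbalance
level used in the class-balancing illustration), noise sd 0.05.
`exact_background_fraction` deterministically flips boundary pixels after
drawing until the background count equals round(target·H·W) — the
all-background-classifier illustration needs the fraction exactly.

Patient series: each patient draws a geometry sub-seed from the master
seed; that patient's slices use consecutive slice seeds and a shared,
reduced jitter, so slices within a patient are measurably more similar
than slices across patients — the correlation structure that makes
patient-wise cross-validation necessary.

Perturbations give predictions with *known* error structure: eroding
class c by radius r produces only false negatives for c, dilating only
false positives, which is what the FP/FN-weighted loss needs for directed
tests. Augmentation samples one affine transform (translation ≤ 10 px,
rotation ≤ 10°, shear ≤ 10 px, scale ≤ 10%) applied identically to image
(bilinear) and labelmap (nearest-neighbour — any interpolation inventing
label values would be invalid), background-filled outside the canvas.

What the phantoms do **not** model: anatomy, intensity nonuniformity,
partial-volume boundaries, inter-scanner variation, 3-D slice geometry.
A green phantom test establishes the arithmetic and the qualitative
mechanics of a loss, never a clinical performance claim.

## Protocol and statistics

Patients (never slices) are shuffled and dealt round-robin into k folds
(sizes differing by ≤ 1); each condition trains on k−1 folds and tests on
the held-out fold, and all conditions share fold plans and seeds so
differences are attributable to the loss alone. The uniclass derivation
relabels every class except the target as background, one binary problem
per foreground class. The α sweep evaluates α ∈ {0, 0.25, …, 2} with
β = 2−α (9 points at step 0.25).

Fold statistics: mean, sample (n−1) standard deviation, 90% CI as
mean ± t(0.95, n−1)·s/√n, and a two-sided two-sample pooled-variance
t-test against a reference condition. The pooled two-sample test is a
choice — the underlying study never names its test — made because it
reproduces the published order of magnitude on the published fold values
(verified independently against R's `t.test(var.equal=TRUE)`), where a
paired test does not. The published asymmetric CI bounds cannot be
produced by any symmetric Student-t formula and are not reproduced.

## Training harness

No deep-learning framework is used: the segmenter is a per-pixel linear
softmax classifier over a fixed feature bank (bias, intensity, Gaussian
smoothings at σ = 1, 2, 4, gradient magnitude, normalised coordinates),
trained by SGDM (momentum 0.9) with the piecewise schedule
lr → 0.9·lr every 20 epochs. The defaults keep the reference recipe
(initial rate 0.005); desk-scale runs pass larger explicit rates (0.5–1.0)
because the count-loss gradients of a linear model at 32×32 are orders of
magnitude smaller than what that recipe was tuned for. The gradient flows
analytically: loss → scores (losses module) → softmax Jacobian → linear
weights. Minibatches are whole images.

**The all-background plateau.** From a near-uniform cold start, the
class-averaged soft IoU/dice losses are *reduced* by collapsing to the
all-background prediction: the background term's gain outweighs the
foreground terms' loss, and the escape gradient afterwards scales like
1/(β·FNc), so FN-heavy weightings deepen the plateau. Count-family
conditions in the pipeline therefore fine-tune from a short crossE warm
start (shared per fold across conditions), mirroring the universal
practice of training segmentation networks from pretrained weights. A
related capacity effect is visible in the demo pipeline: soft count
losses reward *confident* predictions, and when the linear model cannot
make a low-contrast class confident, the background-included average
prefers sacrificing it entirely — the noBK variant, with no background
term to appease, preserves it. This is the background-dominance mechanism
the loss family exists to counter, amplified by small model capacity.

## Directional experiments

Two stochastic, scaled-down analogues of the reported loss-variation
effects, each judged by the median over 5 seeds (≥, ties allowed) on
held-out patients, 32×32 phantoms, 14 slices per trial:

* **FN weighting favours recall**: with an erosion-biased initialisation
  (crossE warm start trained on eroded groundtruths, so the initial model
  under-segments), fine-tuning with (α, β) = (0.5, 1.5) yields foreground
  sensitivity ≥ (1.5, 0.5).
* **noBK favours tiny structures**: on 96%-background 3-class phantoms,
  dice noBK reaches foreground mean IoU ≥ dice with background.

These are directional claims only; no absolute score from GPU-scale
training on clinical data is reproduced or claimed.

## Numerical choices

* ε = 1e-6 in all per-class ratios and as the crossE log clamp.
* Undefined metric = NaN; excluded from means; background id defaults to 0
  and is configurable per class set.
* Confusion counting is a single vectorised bincount over joint codes;
  the test oracle is an independent per-pixel double loop.
* All generators and training runs are deterministic under their seeds
  (numpy default_rng throughout; patient seeds drawn below 2^31).
* Labelmaps interchange as indexed PNG (palette index = class id,
  lossless); multi-channel inputs are rejected rather than converted.

## Known limitations

* The harness's linear capacity makes absolute scores incomparable to
  deep-network results; only arithmetic identities and directional
  effects transfer.
* The soft-loss plateau analysis above is specific to class-averaged
  count losses; focal/boundary/compound losses are out of scope.
* `dice_xy` and `IoU noBK` are expressible via the parameterisation but
  are not preset conditions.
* ROC/AUC beyond point FPR/TPR values is out of scope by design.
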