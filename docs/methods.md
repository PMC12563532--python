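# Methods

This note records the modeling choices behind `ltssl`: what each component
assumes, which knobs matter, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Model and procedure

Training maintains a student network (gradient-updated) and a teacher
network (EMA of the student, decay 0.99 per step, gradients never flow into
it). Every step draws a fixed-composition batch — 12 labeled and 36
unlabeled images by default — and each image is perturbed twice,
independently, for the two networks (random crop-and-resize up to 15% of
each side, horizontal flip with probability 0.5, ±0.1 brightness and
contrast jitter, Gaussian blur with σ up to 0.8 px). The teacher is
initialized as a copy of the student; a config flag allows independent
initialization instead, but a shared start is the convention we follow
because EMA from a common point keeps the early consistency targets
meaningful.

The objective is `L_sup + λ(t)·L_cs + β·L_scl + ζ·L_pl` with β = 0.5 and
ζ = 0.25 by default.

**Supervised term.** Conventional cross-entropy −Σ y log p (mean over
labeled samples); per-class binary cross-entropy in multi-label mode.
Probabilities are clipped to [1e−7, 1 − 1e−7] before any logarithm,
everywhere in the package.

**Consistency term.** Mean squared Euclidean distance between student and
teacher probability vectors (post-softmax / post-sigmoid — consistency is
enforced on predictions, not logits), over the full batch, labeled and
unlabeled alike. Its weight follows the Gaussian ramp
λ(t) = exp(−5(1 − t/T)²), reaching 1 at epoch T and staying there. The
ramp counter is epochs, not steps.

**Supervised contrastive term.** Student and teacher embeddings of the
labeled sub-batch are row-normalized to unit length (configurable off;
normalization bounds all similarities in [−1, 1] and keeps the
exponentials stable), stacked into Z ∈ R^{2N×d}, and scored with

    −(τ/τ0) · (1/2N) Σ_i (1/Σ_j M_ij) Σ_j M_ij ·
        log[ exp(S_ij/τ) / Σ_{k≠i} exp(S_ik/τ) ]

where S = ZZ⊤ and M = YY⊤ − I on the duplicated label rows. Decisions
embedded in that formula:

- The denominator excludes only the anchor itself (k ≠ i). This is the
  standard supervised-contrastive convention and the only reading
  consistent with subtracting the identity from the mask.
- Anchors with no positive partner are skipped (contribute 0) rather than
  raising, so small or all-distinct batches remain usable; a batch with no
  positives at all scores 0.
- For multi-label data M_ij counts the overlapping classes and is used as
  a weight as-is; `binarize_mask` clamps it to {0,1} for the conventional
  binary behavior.
- The prefactor τ/τ0 is kept literal; dividing τ0 by c scales the loss by
  c exactly, which the tests pin down. Defaults τ = 0.1, τ0 = 0.07 are
  implementation defaults (common contrastive-learning settings), not
  values with any external authority.
- The embedding z is a linear projection head (default 64-d) on the
  encoder's last hidden layer. Where the tap point sits is an open design
  choice; the penultimate layer is the usual one.

**Class-adaptive pseudo-label term.** Teacher probabilities on the
unlabeled sub-batch are thresholded per class with

    ε_c(t) = ε_min + (ε_max − ε_min) · min(t/E_ramp, 1) · [1 + 0.1(1 − v_c)]

clipped to [ε_min, 0.99], v_c the normalized inverse class frequency
computed from the training-set class counts. Entries above ε_c become
positive pseudo-labels; entries below 1 − ε_c pass the confidence mask as
negatives; everything else is ignored. Each surviving entry is weighted by
ω = 1 − H(p′) with H the base-2 binary entropy — base 2 is chosen so both
H and ω live in [0, 1]; a natural log would leave ω ≥ 1 − ln 2 and never
reach zero — and scored with the focal term −α(1−p_t)^γ ln p_t against the
student (α = 0.25, γ = 2, the standard focal settings; α is constant, not
scheduled). Everything is per class, one-vs-rest, also for single-label
heads (no cross-class argmax consistency is imposed), and the term
activates only from `capr_start_epoch` (default: when the consistency ramp
ends), since early pseudo-labels amplify their own errors.

Two threshold-formula choices deserve emphasis:

- The ramp uses min(t/E_ramp, 1). The max variant (available as
  `literal_max`) pins the schedule at its ceiling from epoch 0 and makes
  the ramp length inert, which contradicts the point of having a ramp.
- The bracket [1 + 0.1(1 − v_c)] ≥ 1 pushes every class's ceiling *above*
  ε_max; the upper clip at 0.99 keeps the confident-negative band
  1 − ε_c nonempty. A consequence worth knowing: the fully ramped
  threshold of every class, tail included, exceeds ε_max, so the schedule
  is uniformly stricter than a fixed threshold at ε_max — its
  class-adaptivity acts by *suppressing head-class* pseudo-labels relative
  to tail ones, never by admitting tail pseudo-labels more readily than
  the fixed rule would.

**Reduction of the pseudo-label loss.** The loss is a bare sum over
samples × classes (mean available via `FocalConfig.reduction`). The sum is
deliberate: the confidence mask admits many near-zero confident-negative
entries, and a mean over mask-passing entries divides the few informative
ones (teacher confident, student not) down by that count — in our
experiments this collapsed the term to ~1e−5 against component losses of
order 1, rendering it inert.

**Optimization.** Adam (lr 1e−3, default betas), exponential decay ×0.9
per epoch, gradient steps on the student only, EMA after every step. The
learning rate suits the small from-scratch backbone used here; transfer
settings with pretrained deep backbones conventionally use 1e−4.

## Networks

No deep-learning framework is a dependency, so the package carries a
minimal reverse-mode autodiff engine over float64 NumPy arrays
(`ltssl.autodiff`; every operator is finite-difference-checked in the test
suite) and a fully-connected backbone: flattened pixels → hidden layers
(256, 128) with ReLU → linear classifier head + linear projection head.
The trainer only requires `forward(x) -> (logits, embedding)` and
`parameters()`, so convolutional or pretrained backbones can be plugged in
where a framework is available.

## Synthetic data

Each class is a fixed smooth random spatial pattern (Gaussian-filtered
noise, zero mean, unit peak); a sample is 0.5 + contrast·prototype +
N(0, σ²) per pixel, clipped to [0, 1]. Class sizes follow
n_c = max(head·ratioᶜ, min_count) — the default spec gives counts
[400, 200, 100, 50, 25]; explicit count vectors (e.g. real dataset
frequencies with a ~58:1 head-tail span) can be passed instead. Multi-label
mode superimposes a second prototype with configurable probability. The
held-out test split is balanced per class so macro metrics are estimated
with equal precision everywhere; 100 images per class resolves per-class
recall at 0.01.

The contrast/noise pair (0.3 / 0.45) was fixed once from a linear-probe
span check: a pixel-level logistic probe reaches 1.0 test accuracy at zero
noise, ~0.92 when trained on the full default training set, ~0.59 when
trained on its 20% labeled subset, and chance at large noise. That leaves
the gap between "few labels" and "all data" that semi-supervised learning
is supposed to close.

What the generator does **not** emulate: natural image statistics,
intra-class style variation (all samples of a class share one prototype),
label noise, and resolution/scale effects. Passing directional experiments
on this data shows the training mechanics behave as designed — it does not
predict effect sizes on dermoscopy or radiographs.

## Evaluation

Per-class one-vs-rest AUC (rank-based, midrank ties, via scikit-learn),
sensitivity, specificity, accuracy, precision and F1 from argmax
predictions (single-label) or a 0.5 threshold (multi-label), aggregated as
unweighted macro means — frequency-weighted averages would hide exactly
the tail behavior the method targets. A class with a single label value in
the test set has undefined AUC: reported as missing, excluded from the
macro mean, with a warning. The evaluated network is the student (the
teacher is available via config).

## Scale of the shipped experiments

The reference experiments (tests and `scripts/acceptance.py`) use the
default generator (775 training images, 20% labeled), the (256, 128)
backbone, 30 epochs with a 10-epoch ramp and pseudo-labeling from epoch 10,
three seeds per configuration — a few minutes on one CPU in total. These
sizes are the package's desk-scale reference conditions; the epoch:ramp
ratio mirrors the conventional 100:30 / 20:10 protocols.

## Known limitations

- At desk scale the softmax of a small from-scratch network rarely exceeds
  0.95, so few positive pseudo-labels pass the fully ramped thresholds;
  the adaptive-vs-fixed-threshold contrast on tail recall is correspondingly
  weak (the suppression of head-class pseudo-labels is observable in the
  pseudo-label counts, but its effect on tail predictions is within seed
  noise). Confidence-saturated backbones are where the adaptive schedule
  has room to act.
- The contrastive term uses only labeled samples by design; it cannot help
  when labels are extremely scarce in absolute terms (a class with one
  labeled sample has no positive pair except its own teacher view).
- The autodiff engine is eager and unoptimized; it is adequate for the
  shipped problem sizes, not for 224×224 inputs.
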