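# Methods

## Problem

Glomerular histopathology patches carry annotations for many structure
classes — region tissue (Bowman's capsule, tuft, mesangium), cells
(podocytes, mesangial cells) and lesion categories — but each annotated
patch is labeled for **exactly one** class.  The classes are not mutually
exclusive: the capsule contains the tuft, the tuft contains the mesangium,
and lesions overlap all of them, so per-pixel softmax segmentation is the
wrong model.  `glomseg` implements a single network that treats each class
as a *task*, learns all tasks from the one-label-per-sample stream, and can
emit an independent (possibly overlapping) binary map for every class.

## Model

**Backbone.**  A residual U-Net: a stem convolution, `depth` encoder stages
(pre-activation residual block, then a stride-2 convolution that doubles
width), a bottleneck residual block producing the feature map `F`, and a
mirrored decoder (nearest-neighbor 2× upsampling, skip concatenation,
residual block) ending in a 1×1 convolution that produces the
`D`-channel full-resolution feature map `M`.  Normalization is per-instance
rather than per-batch because batches mix classes and domains at batch
size 4, where batch statistics are unreliable.

**Task encoding.**  Class `i` of `m` is encoded as the one-hot vector
`T_i ∈ {0,1}^m`.  The task dimension always spans the full catalog, even in
runs that train only a subset of classes, so checkpoints from different
training subsets remain interchangeable.

**Controller and dynamic head.**  The controller is a single convolutional
layer `ϕ` applied to `[GAP(F) ∥ T_i]` (a 1×1 spatial map, so the
convolution is an affine map), emitting a flat vector

    ω = ϕ(GAP(F) ∥ T_i; Θ_ϕ),   |ω| = N = (D·c1 + c1) + (c1·c2 + c2) + (c2·c3 + c3)

which is split into the weights and biases of three 1×1 convolution layers
(ω1, ω2, ω3) applied to `M`:

    P = σ( M * ω1 * ω2 * ω3 )

with a rectifier after the first two layers and none after the third (the
logits must be unbounded for the sigmoid/Dice losses).  Default head widths
are `(c1, c2, c3) = (8, 8, 1)` with `D = 8`, giving `N = 153`.  The
controller's initial weights are scaled down by 10× relative to He
initialization: the generated kernels multiply through three layers, and a
full-strength start saturates the sigmoid on the first forward pass.

**Multi-head baseline.**  The ablation comparator shares the backbone but
replaces controller + dynamic head with one fixed 1×1 convolution emitting
all `m` channels; only the annotated channel of each sample is supervised.

## Training on partial labels

**Image pool.**  The training stream is buffered in a pool whose capacity
equals the number of involved classes; whenever the buffer exceeds the
batch size (default 4), a batch is drawn uniformly without replacement.
This decorrelates the class composition of consecutive batches without
requiring a class-balanced sampler.  Residual buffered samples carry over
between epochs.

**Loss.**  Per sample, the prediction for the annotated class only is
scored with equal-weighted soft-Dice (smoothing constant 1) plus binary
cross-entropy; unlabeled classes receive no gradient from that sample.  The
batched loss is exactly the mean of per-sample masked losses (verified by a
gradient-isolation test).

**Optimization.**  Adam, learning rate 1e-3, no schedule, with global-norm
gradient clipping at 1.0.  Clipping matters here: the controller's gradient
scale can spike on hard batches (its output multiplies through three
generated layers), and unclipped runs occasionally collapse late in
training to the all-background solution.  All randomness — weight
initialization, epoch shuffling, pool draws — derives from one master seed.

**Model selection.**  Each epoch is scored by per-class validation Dice
(classes absent from validation are excluded with a warning); the snapshot
with the highest mean is kept, ties resolved to the earliest epoch.

## Evaluation

Dice = 2|P∩G| / (|P|+|G|) on binarized maps (threshold 0.5).  Conventions
for degenerate masks: both empty → 1.0; one empty → 0.0.  Per-class scores
are means over that class's samples; the summary is the unweighted mean
over classes (not samples), mirroring the "Average" column of segmentation
tables.  Reported tables use percent with one decimal.

## Synthetic phantoms

Real glomerular datasets are private, so the package ships a seeded
generator of phantoms that reproduce the statistical structure the method
exploits, deliberately not histological appearance:

- nested ellipses with strict containment (mes ⊆ tuft ⊆ cap), enforced by
  intersection during construction;
- cell disks scattered inside the tuft;
- five lesion archetypes keyed to shape: *global* (a concentric ellipse at
  0.97 linear scale, covering ≥ 90% of the capsule by area), *segmental*
  (an angular sector of the tuft), *nodular* (a compact disk), *hyaline*
  (a smooth blob at the tuft boundary), *microaneurysm* (a small disk);
  the annotated lesion is always present and the others appear with
  probability 0.25;
- flat per-structure colors separated enough that a trivial color-threshold
  classifier exceeds 95% capsule-vs-background accuracy (so the learning
  task is provably solvable), plus Gaussian pixel noise (σ = 0.02);
- two domains: the target is shifted by a fixed affine color transform
  (offset (−0.06, +0.04, −0.08), intensity ×0.92), geometric scale ×1.15
  and noise σ = 0.03 — the smallest shift family that makes zero-shot
  transfer measurably worse than hybrid training;
- partial labels: each emitted patch annotates one class (cycling through
  the requested classes), with the full ground truth retained for
  containment-aware tests;
- synthetic patients: blocks of 4 consecutive samples share a patient id,
  enabling patient-level split tests.

What passing tests on phantoms do **not** show: robustness to staining
variability, nuclear texture, annotation noise, or morphology that varies
continuously between classes.  The phantoms certify the machinery
(task-conditioned kernels, partial-label training, transfer protocol), not
clinical performance.

## Reference protocols and problem sizes

Two fixed desk-scale experiments (`glomseg.protocols`) define the
conditions under which the package's claims are checked; both use a
depth-3, width-8 backbone with `D = 8` — a size chosen so the full suite
runs on one CPU core in minutes:

- **Learnability**: 200 one-label 64×64 phantoms over five classes (three
  nested regions + global and nodular lesions), 40 validation and 40 test
  samples from disjoint synthetic patients, 30 epochs.  Expected outcome:
  mean held-out Dice ≥ 0.70 and far above the untrained network.
- **Transfer**: lesion-only phantoms at 32×32 with 100 source and 20 target
  training samples (1:5 target:source), 20 source-val / 8 target-val
  samples, a fixed 32-sample target test split, 12 epochs, three seeds.
  Expected outcome: hybrid source+target training is at least as good as
  zero-shot source-only transfer on the target test set; this is
  simultaneously the dynamic-head "both vs source-only" ablation ordering.

The splitting rule used throughout is largest-remainder apportionment of
the 6:1:3 ratio over patients with a seeded shuffle; the phantom protocols
assign whole patient blocks to splits directly, which is equivalent and
keeps exact sample counts.

## Numerical and design notes

- The network runtime is a purpose-built tape-based reverse-mode autodiff
  over numpy (im2col convolutions, hand-written backward passes); every
  primitive is verified against central finite differences, and the
  dynamic head against an independent per-pixel brute-force oracle.
  Training arithmetic is float32; evaluation sigmoids are computed in
  float64 with a branch-stable logistic.
- Binarization threshold is fixed at 0.5 for all classes.
- The pool draw is uniform without replacement; no class-balancing is
  applied beyond what the pool's mixing provides.
- A checkpoint embeds the backbone config, head widths and a catalog hash,
  and refuses to load against a different catalog.
- Known limitations: no augmentation, no learning-rate schedule, no
  spatial (>1×1) dynamic kernels, no transformer backbones, and no
  whole-slide reading or detection stage — inputs are pre-cropped patches.
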