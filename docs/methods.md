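# Methods

This note records the modelling and numerical choices behind the
package, the parameters that matter, what the synthetic data does and
does not emulate, and the known limitations.

## Architecture

The backbone is a compact DenseNet variant: a stem block, then six
phases of dense blocks, with transition blocks after phases 1–5 only.
The channel arithmetic is exact and is exposed as a pure calculus
(`infer_feature_shapes`) independent of the tensor engine: a dense phase
with n base blocks grows channels by n·k (k the growth rate), a
transition preserves channels (compression factor 1 by default, an
option since DenseNet-style compression < 1 is common elsewhere) and
ceil-halves the spatial side. Ceil rounding is the only convention that
produces the 75 → 38 and 5 → 3 side transitions of the reference
geometry, so it is used for every stride-2 stage (TF-style SAME padding
in the convolutions, edge-padded pooling windows with the padding
excluded from average-pool divisors).

**Stem topology.** The stem's published description fixes its contract —
(299, 299, 3) → (75, 75, 96), first convolution 64 filters, an
asymmetric Inception-style kernel pair — but not its exact layer list.
We use: 3×3 stride-2 (64) → 3×3 (64) → 1×7 (64) → 7×1 (64) → 3×3
stride-2 (96), ReLU after each. The contract, not the topology, is the
tested surface; the fallback entry with the stem disabled is the
conventional 7×7 stride-2 convolution + 3×3 stride-2 max pool with the
same output contract.

**Base-block ordering.** Inside a base block the order is ReLU → 1×1
conv (4k) → 3×3 conv (k), taken as listed in the architecture's
description rather than the pre-activation DenseNet ordering; no
activation sits between the two convolutions. When batch normalization
is enabled (an ablation option, off by default because the
best-performing reported configurations omit it) a BN stage precedes
each convolution.

**Pyramid level 6.** The deepest backbone map (3×3×576 at full input
size) is reduced to the 1×1 pyramid level by one extra 3×3 valid
convolution (256 filters) — the minimal reading of "additional
convolution layers" consistent with the published level sizes. For
reduced inputs whose phase-6 map is smaller than 3×3 the kernel shrinks
to the map side so the deepest level is always 1×1.

**Input-size domain.** Inputs below 129 pixels are rejected: after the
stem's two halvings and five transition halvings the phase-5 output
would drop under 2 pixels and the six pyramid levels could no longer be
strictly decreasing. 299 (the published size) and 149 (the reduced
variant used by the scaled-down tests) both lie in the valid domain.

## Numpy layer engine

No deep-learning framework is used: convolution is im2col plus a BLAS
matmul, with manual backward passes for every layer (verified against
central finite differences in the test suite at float64). Weights are
He fan-in initialized from a seeded `numpy.random.Generator`; all
randomness in the package flows through explicit generators, so every
artifact — synthetic frames, splits, weight init, batch sampling — is a
pure function of its seed. Forward/backward run in float32; the loss and
its analytic gradients are computed in float64 for stability.

## Default boxes, matching, codec

Three boxes per location: ratio 1 at the level scale s_k, ratio 1 at the
intermediate scale √(s_k·s_{k+1}), ratio 2 at s_k — the literal reading
of "aspect ratios between one and two" (ratio 1/2 is excluded; the ratio
set is configurable). Scales are linear from 0.2 to 0.9 and the offset
variances are (0.1, 0.2), both the canonical SSD settings, since the
source gives none. Matching force-assigns every ground truth to its
best-IoU default (lowest-index tie-break) and additionally marks any
default with IoU ≥ 0.5 positive — the threshold mirrors the evaluation
IoU. NMS defaults: confidence floor 0.01, IoU threshold 0.45, top-200
pre-keep, final keep 100.

Boxes are 0-based half-open pixels internally and normalized [0, 1] at
the codec boundary; Pascal-VOC XML on disk is 1-based inclusive, with
the conversion (xmin−1, ymin−1, xmax, ymax) applied on read and inverted
exactly on write.

## Loss

Confidence and localization terms are both normalized by the batch
positive count (zero positives ⇒ zero loss); smooth-L1 transitions at 1;
negatives are mined per image among non-positive boxes by descending
cross-entropy, capped at 3 per positive. Forced-positive boxes (best
match for some ground truth but IoU < 0.5) are positives and therefore
excluded from the mining pool.

## Evaluation

Detections are matched in descending score order; each ground truth is
claimable once, so duplicates are false positives; "IoU greater than
0.5" is implemented boundary-inclusive (≥ 0.5). AP uses 11-point
interpolation by default, matching the detector generation this model
belongs to; an all-point variant is exposed because the two differ by a
point or two of mAP. FPS is wall-clock frames over seconds with one
warm-up call excluded, and is only ever reported, never asserted — it is
hardware-bound. Published per-dataset P/R/F1 tables for this detector
family are not all internally consistent under F1 = 2PR/(P+R); the
package reports P, R, F1, and mAP separately and makes no attempt to
reconcile such rows.

## Training

Adam (0.9, 0.999, 1e−8), batch 32, 100 epochs × 500 steps, and the
piecewise learning-rate rule (1e−4 / 1e−5 / 1e−6 with breaks at epochs
80 and 100) are the full-scale defaults. The published recipe also
mentions a 0.5-per-10-epochs decay; the piecewise rule is stated as the
operative one, so it is the default and step decay is kept as a config
option. Dataset handling follows the published protocol: 70/10/20
train/val/test split, with five-fold cross-validation available within
the training portion. Validation mAP is computed each epoch and the
best-mAP weights are checkpointed.

## Synthetic data

The generator renders what the pipeline needs from endoscopy-like
frames: a warm mucosa-toned base with two scales of smoothed noise and a
radial vignette; one or two elliptical polyp blobs (default radius 7–17%
of the image side, contrast 0.25–0.55) with a textured interior and a
darker rim; optional bubble rings, specular highlights, and a black
circular border. Ground-truth boxes are the tight bounding boxes of the
rendered polyp masks, so they are exact by construction. Rendering is
byte-deterministic per seed.

What it does not emulate: real mucosal vasculature and folds, motion
blur, debris, lighting extremes, flat/sessile polyp morphology, and
inter-patient variability. Passing tests on this data demonstrate that
the pipeline is mechanically correct and trainable, not that the
detector reaches clinical-grade accuracy; that claim would require the
real WCE/colonoscopy corpora and full-scale training.

## Problem sizes in the tests

The end-to-end checks train the reduced 149×149 input variant, batch 4,
for 50 steps on 16 synthetic frames — large enough for the loss to fall
by far more than half and for validation mAP to rise orders of magnitude
above an untrained checkpoint, small enough to run in about a minute on
one CPU core. The architecture checks run the full 299×299 model; a
single forward pass takes a few seconds in this engine.

## Known limitations

- The engine is CPU-bound and single-image latencies are far from the
  real-time figures achievable with GPU frameworks; FPS numbers from
  `measure_fps` characterize this implementation only.
- Batch statistics (BN) use a fixed 0.9 running-stat momentum; with BN
  enabled, train/eval outputs differ as usual.
- `match_targets` resolves competing forced matches greedily in
  ground-truth index order; with heavily overlapping ground truths a
  different assignment could in principle score higher IoU in aggregate.
- Rows of one batch can differ from a single-image forward pass by
  float32 accumulation order in the underlying BLAS; all determinism
  guarantees are at fixed batch composition.
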