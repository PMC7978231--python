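# Methods

## Model and training procedure

The classifier is a shared convolutional feature encoder with two affine
heads: a 2-logit supervised head for the lesion classes and a (P+1)-logit
jigsaw head for the pretext task. Training alternates within every
iteration: one supervised step on a mini-batch of the selected labelled
subset D_K (weighted cross-entropy, updating encoder + supervised head),
then one unsupervised step on a mini-batch drawn from all training frames
(labelled and unlabelled, validation excluded), passed through the jigsaw
shuffler and scored by the λ-scaled weighted jigsaw cross-entropy (updating
encoder + jigsaw head). Each phase touches only its own head, so the other
head's parameters are bit-identical before and after — a property the test
suite checks directly. Supervised batches are never scrambled; test images
are likewise always presented in their original tile order.

The jigsaw head has P+1 outputs rather than P: the pseudo-label set is
{0, …, P} with index 0 the unscrambled image, and the unsupervised loss sums
over all P+1 classes, so the identity must occupy its own output. The epoch
length is set by the unsupervised stream (⌈|pool|/batch⌉ iterations); the
smaller D_K stream cycles with reshuffling so each iteration pairs one batch
of each kind. In baseline mode (no jigsaw head) an epoch is one pass over
D_K.

Assumptions inherited from the method: frames of one video are near
duplicates of one lesion, so all data routing is at video level; the class
signal is carried by global shape/texture cues that survive tile scrambling
as *content* but are destroyed as *layout*, which is what makes permutation
prediction informative for the supervised task.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| grid_size | 3 | 3×3 tile grid; 222 px input divides into 74 px tiles |
| P | 30 | scrambled permutations (pseudo-label classes); the low-label operating point |
| s | 0.6 | scrambled fraction of an unsupervised batch |
| patch scale | 0.75–0.9 | tile-jitter crop range; breaks edge-continuity cues |
| λ0 | 1.5 | unsupervised loss weight |
| λ growth | off | ×1.5 every 5 epochs when on (low-label regime) |
| lr | 1e-4 | default optimiser step (adaptive moments, decoupled weight decay) |
| batch_size | 32 | unstated in the underlying protocol; conventional choice |
| k_fraction | 100 | % of labelled training videos used for supervision |

The desk-scale experiments shipped with the package use lr = 1e-3: the
default 1e-4 presumes a pretrained backbone, while the small from-scratch
backbones here need the conventional from-scratch Adam rate. Weight decays
in the experiment scripts follow the per-k operating points of the
underlying protocol (0.2 for the SSL model and 0.005 for the baseline at
k = 6.25%, 0.005 at k = 100%).

Class weights for the supervised loss are recomputed from the frame counts
of each run's D_K (w_c = 1/freq(c)); the global 0.83 : 0.17 figure is the
full-data instance of the same rule.

## Permutation selection

Greedy max–min Hamming selection: start from a uniformly random
non-identity permutation, then repeatedly add the candidate maximising the
minimum Hamming distance to the already-selected set, breaking ties toward
the lexicographically smallest candidate (determinism). For grids with
n_tiles! ≤ 10,000 the candidate set is exhaustive; for the 9-tile grid each
round scores a seeded uniform sample of 100,000 permutations, keeping the
selection O(seconds) on one core. For n_tiles ≤ 4 the implementation is
verified against an independent exhaustive greedy oracle.

## Backbones

Two numpy backbones are provided, both taking normalised 3×222×222 input:
`tiny-conv` (6× average-pool, two 3×3 conv blocks, flattened 5×5 map →
64-d features) and `small-residual` (two residual conv blocks, 128-d
features). Feature maps are flattened, not globally pooled: global pooling
would discard the spatial layout the jigsaw task must read. The engine
(conv via im2col, explicit backprop, AdamW) is float32 and fully
deterministic; all weights derive from per-parameter named seed streams, so
a model with and without a jigsaw head has identical encoder and supervised
weights at initialisation — the basis of the exact baseline-reduction check.

## Data selection and cross-validation

20% of labelled training videos are first held out for validation,
stratified by class, fixed per fold and identical for every k. D_K then
takes the first ⌈k% · n⌉ remaining videos per class in a seeded order, so
selections are nested across k for a fixed fold/seed. Metrics are
frame-level; accuracy, F1, sensitivity, specificity and precision follow
the standard confusion-count closed forms, with zero-denominator ratios
reported as NaN and flagged rather than silently zeroed. AUROC is the
Mann–Whitney pairwise probability with ties at 1/2 (argmax prediction ties
break toward the negative class, the conservative choice for specificity).

In domain-adaptation mode the supervised stream uses labelled source-domain
(WLI) videos only; the unsupervised pool is labelled source ∪ unlabelled
target frames, and held-out labelled target frames form the test set. A
counter audits that no target frame ever enters a supervised batch. For
WLI-restricted selections the validation split uses 3 folds instead of 5:
under the 0.83 : 0.17 imbalance the single-domain negative class has too
few videos for a 5-way video-level partition.

## The out-of-distribution score

κ = KL[U‖p(y|x)] + w₀·(−log p_jigsaw(0|x)), natural logs, probabilities
clamped at ε = 1e-12. The second term is evaluated at pseudo-label 0
because test images are never scrambled; w₀ comes from the training-time
jigsaw weights. Note the two terms move in opposite directions for OOD
inputs — the KL term *falls* when predictions become less confident while
the jigsaw term rises — so the score is reported as printed and both terms
are exposed per sample for auditing. On the synthetic benchmark the
ssl-mode AUROC varies strongly across training seeds, which is consistent
with this partial cancellation; the directional claim (SSL ≥ baseline in a
majority of seeds) is what the test suite asserts.

## Synthetic data generator

The generator emulates the structure of a private colonoscopy video
dataset: 60 videos × 15 frames by default, each video one unique lesion;
40% of videos unlabelled; labelled videos 0.83 : 0.17 positive : negative;
60% of videos in a warm broad-band colour domain (WLI-like), the rest in a
green–blue narrow-band domain (NBI-like); 20% of labelled videos per
(class, domain) held out as the test split.

Each lesion is an elliptical blob on a textured mucosa-like background.
Class 1 has a lobulated margin (angular modulation amplitude 0.14–0.26,
3–5 lobes) and coarse internal texture (Gaussian correlation length
4.5–7 px); class 0 a near-elliptical margin (amplitude ≤ 0.07) and fine
texture (1–2.2 px). Both cue distributions deliberately overlap. Appearance
varies strongly between lesions — per-lesion tone jitter, size, contrast
(with a minimum lesion/background chromaticity contrast so every lesion is
visible), off-centre vignetting and specular highlights — so a handful of
training videos cannot span a class's appearance manifold; this, not cue
ambiguity, is what makes the low-label regime hard, mirroring how scarce
labelled lesions limit the real task. Frames of a video are small affine
jitters (±8°, ±6 px, ±5% scale) plus Gaussian pixel noise (σ = 0.03) of one
base render, which enforces the intra-video correlation that makes
video-level splitting matter. A `local_signal_only` switch replaces the
global cues with a small colour patch as a negative control.

What the generator does **not** emulate: real mucosal texture and
vasculature, view-dependent geometry, motion blur, instrument occlusion,
label noise, and the scale of clinical datasets. Passing tests therefore
demonstrate that the implementation behaves as specified and that the
method's directional claims hold under the assumed cue structure — not that
the clinical accuracy figures transfer.

## Problem sizes of the shipped experiments

The directional experiments run on the default 900-frame dataset with the
`tiny-conv` backbone: SSL vs baseline at k = 6.25% for 15 epochs over 5
seeds, and the OOD benchmark (models trained on WLI only, 10 epochs, 5
seeds in the test suite; the acceptance script runs one seed of each).
These sizes keep a full run on one CPU core in the minutes range while
preserving the regime of interest (tens of labelled frames, hundreds of
unlabelled).

## Numerical choices and limitations

ε = 1e-12 probability clamp inside every log; natural logarithm throughout;
crop sides are floored; rescaling is bilinear; tile indexing is row-major,
origin top-left, 0-based. Checkpoint selection keeps the epoch with the
best validation accuracy (earliest on ties). Per-sample Bernoulli(s)
scrambling holds the batch ratio in expectation rather than exactly.
Known limitations: no multi-GPU or large-backbone support (the engine is a
deliberate desk-scale numpy implementation), no ImageNet-pretrained
initialisation, and greedy (not optimal) max–min permutation design.
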