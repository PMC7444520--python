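# Methods

## Problem and model

`painstn` estimates facial pain intensity from single face images on the
four-level scale used in the shoulder-pain literature. Ground truth
comes from FACS action-unit codings: each frame's Prkachin–Solomon Pain
Intensity is

    PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43,

with AU4 (brow lowering), AU6/AU7 (orbital tightening) and AU9/AU10
(levator contraction) on the 0–5 ordinal scale and AU43 (eye closure)
binary, so PSPI ∈ {0, …, 16}. Scores are binned 0 → level 0 (none),
1–2 → level 1 (weak), 3–5 → level 2 (intense), ≥ 6 → level 3
(excruciating).

The classifier is a composition of three stages:

1. **Spatial transformer.** A localization CNN regresses a 2-D affine
   transform θ ∈ R⁶ from the input; a grid generator maps the regular
   output grid through A_θ in normalized [-1, 1]² coordinates
   (align-corners convention, (-1, -1) at the top-left pixel center);
   a bilinear sampler resamples the input at those source locations,
   with out-of-bounds coordinates contributing zero (the black edges
   visible after rotation). The localization net is six blocks of
   (3×3 conv, ReLU, 2×2 max-pool) with 16 filters at the canonical
   192×192 input — spatial trace 192→96→48→24→12→6→3, flatten width
   3·3·16 = 144 — followed by FC(144→32), ReLU, FC(32→6).
2. **Per-channel attention gating.** Each color channel is convolved
   with its own 3×3 kernel (pad 1), squashed by a sigmoid, and the
   channel is multiplied elementwise by the resulting weight map:
   V′ = V ⊙ σ(conv(V)). Gates are unshared across channels (a shared
   variant is available via `share_weights=True`).
3. **Backbone + head.** Six (3×3 conv, ReLU, 2×2 max-pool) blocks with
   filter counts (64, 64, 128, 128, 256, 256) reduce 192×192×3 to
   3×3×256; a single fully connected layer maps the 2304 features to 4
   logits; softmax cross-entropy is the training loss and prediction is
   the arg-max logit (ties to the lowest level).

Reduced-resolution clones use any input size 3·2^k (24, 48, 96, …); the
block count follows from k and the filter schedule is truncated or
overridden. This preserves the architecture's defining property — the
final 3×3 spatial maps — at any scale.

All layers are implemented directly over numpy with explicit backward
passes (im2col convolutions, argmax-routed pooling, analytic sampler
gradients for both the source image and the grid). Every primitive is
tested against a scalar brute-force oracle and finite differences; the
composed network passes an end-to-end gradient check on a 24×24 clone.

### A note on the published layer tables

The reference layer tables list stride 2 on both the convolutions and
the pools, which is inconsistent with their own fully connected
dimensions (192 would collapse below 1 long before the stated 144-wide
flatten). The only consistent reading — convolutions at stride 1 with
padding 1, all downsampling done by the 2×2 pools — is what this package
implements; it reproduces both the 144-wide localization flatten and the
3×3×256 backbone output exactly.

## Training

SGD with classical (heavy-ball) momentum: v ← βv − αg, w ← w + v, with
β = 0.9 and α = 10⁻⁴ by default. Weights are He-initialized — zero-mean
Gaussians scaled by √(2/fan) — with fan defaulting to the full fan-in
k·k·C_in (`fan_mode="channels"` gives the literal input-channel-count
reading); biases start at zero. The localization head starts at zero
weights with the identity transform as bias so training begins from a
no-op transformer (`identity_init=False` disables this). Mini-batches
are reshuffled every epoch; after each epoch the development split is
scored and the best-dev snapshot retained (ties keep the earlier epoch).
Training aborts with a diagnostic if the loss becomes non-finite. There
is no batch normalization, dropout, weight decay or schedule. Runs are
bit-reproducible given the seed.

Two stabilizers specific to the transformer are exposed because its
failure mode is unusual: if θ overshoots, the sampling grid leaves the
image, the output goes black and the gradient through the sampler dies,
leaving the model permanently collapsed onto the majority class.

* `loc_lr_scale` multiplies the learning rate of the localization
  parameters only (default 1.0; the scaled experiments use 0.5 at their
  aggressive global rate).
* `loc_head_damp` controls the identity initialization of the final
  localization FC: bias = identity θ, weights = He init × damp. The
  default damp of 0 gives an exactly identity (no-op) start, but a zero
  head also blocks all gradient into the localization body — the chain
  rule multiplies every body gradient by the head weights — so the
  transformer can then only learn a constant, input-independent
  transform within short training runs. A small damp (0.05 in the
  scaled experiments) keeps the start near-identity while letting
  input-dependent localization emerge.
* `stn_identity_anchor` adds a quadratic penalty
  λ·mean(‖θ − θ_identity‖²) on the predicted transform (default 0).
  The runaway state is *absorbing*: once θ maps the grid outside the
  image the output is black and the sampler gradient is zero, so
  nothing pulls θ back. A small anchor (0.03 in the scaled
  experiments) makes the identity attractive enough to prevent the
  runaway while leaving room for useful learned transforms such as the
  zoom onto a loosely cropped face.

Datasets are split by subject (10/5/10 of 25 by default) so no
identity appears in two splits, and the dominant no-pain class can be
subsampled to a fixed count before splitting (`balance_level0`),
mirroring the archive protocol (40007 → 5260 level-0 frames). The
archive's own subject partition is unpublished, so partitions here are
seeded-random — exact replication of its test population is impossible
by construction.

## Evaluation

Confusion matrices are accumulated with rows = true level, columns =
predicted level. Accuracy, per-level precision and recall are reported
in percent (one decimal for display); precision of a level with a zero
diagonal is defined as 0, covering both 0/0 and the never-correct case.
The ordinal error is the level-index MSE, Σ c_ij (i−j)² / Σ c_ij —
this is the only definition that reproduces the reference MSE of 1.1014
from its printed matrix, which is why it is used rather than raw-PSPI
MSE. Feature scatters project the 4-logit layer to 2-D by PCA with a
deterministic sign convention (largest-magnitude loading positive).

The embedded reference matrices (`painstn.published`) carry known
internal inconsistencies, kept verbatim: the no-STN-no-attention matrix
has inconsistent row sums and its reported 32.7% accuracy cannot be
recomputed from it; two reported MSEs (1.4033, 1.3185) do not match
their matrices; the LBP and region-CNN matrices recompute 0.1 below
their reported accuracies. Tests assert the recomputed values and treat
the discrepancies as documented anomalies.

## Synthetic faces

The real archive is access-restricted, so the generator draws schematic
faces from geometric primitives with the statistical structure the
method assumes:

* **AU-driven geometry.** AU4 lowers, thickens and tilts the brows;
  max(AU6, AU7) narrows the eye apertures; AU43 replaces the sclera
  with a closed-lid line; max(AU9, AU10) raises and opens the mouth and
  widens/darkens the nose wedge. All deformations are monotone in
  intensity, and every frame's label is recomputed from its stored AU
  record, so label integrity is checkable.
* **Loose-crop framing.** `face_scale` (default 0.7) shrinks the face
  within the frame, emulating loose face crops from video where
  substantial background surrounds the face — the condition under
  which the transformer's crop/zoom behaviour has value.
* **Affine nuisance.** Each frame is resampled through the package's
  own grid generator and bilinear sampler with a random affine drawn
  from (±35° rotation, ±25% translation, ±20% scale, ±0.15 shear).
  These ranges were fixed after verifying that milder ranges left a
  baseline CNN essentially unaffected — a nuisance the transformer is
  meant to undo must actually hurt a model that cannot undo it.
* **Clutter and identity.** Random colored rectangles/ellipses fill the
  background (density-controlled); colors span the RGB cube including
  skin-like tones, since gray-only clutter proved trivially separable
  from the face and degraded nothing. Per-subject jitter of face
  proportions (±8–12%) makes subject-disjoint splits non-trivial.
* **Class mix.** Levels are drawn i.i.d. from the archive's portions
  (82.7/10.9/5.1/1.3%) by default; experiments use the post-balancing
  mix (5260, 5260, 2456, 653)/13629. AU codings for a requested level
  are allocated unit-by-unit at random among AU4, max(AU6, AU7),
  max(AU9, AU10) and AU43 until the drawn PSPI target is reached.

What the generator does **not** emulate: real facial texture, lighting,
3-D pose, occlusion, temporal dynamics, or correlated AU co-occurrence
statistics. Passing the synthetic experiments therefore demonstrates
that the pipeline's mechanics work (gradients flow, the transformer can
learn to help under affine nuisance, attention can help under clutter,
labels bind correctly) — not that the reported archive accuracies would
be reproduced on real video, which also requires the restricted data.

## Scaled experiment protocol

Training the full 192×192 architecture on tens of thousands of frames
is not a desk-scale computation in pure numpy, so the learning
experiments run a reduced clone chosen to preserve the study's
structure: 48×48 inputs (four blocks), localization width 8, backbone
filters (8, 16, 16, 32), 600 frames over 25 subjects split 10/5/10,
batch 32, 30 epochs, learning rate 10⁻² with `loc_lr_scale` 0.5,
`loc_head_damp` 0.05 and `stn_identity_anchor` 0.03, float32
arithmetic. Five seeds
are averaged for the ablation ordering (one shared dataset per seed
across the four modes, so comparisons are paired). The development and
test pools are generated twice as large as the training pool — same
subjects, same deterministic generator stream — so snapshot selection
and the reported accuracies are less noisy at unchanged training cost
(~240 training, ~240 dev, ~480 test frames per seed). The learnability
floor uses 500 frames of levels {0, 3} at quarter-strength nuisance and
20 epochs. The package defaults remain the reference recipe (192×192,
full widths, α = 10⁻⁴); every experiment override is an explicit,
config-exposed argument.

At this scale the single-stage effects are small relative to seed-level
training variance, so the ablation is read directionally (ordering of
seed-averaged means), and hair-thin margins between individual modes
should not be over-interpreted; the combined model placing first and
the plain backbone last-or-tied is the stable part of the picture.

## Numerical choices and edge cases

* float64 everywhere by default; float32 opt-in for speed (used by the
  scaled experiments). Gradient checks run in float64.
* Bilinear sampling is non-differentiable exactly at integer pixel
  coordinates (floor kinks); finite-difference checks avoid lattice
  points. The identity-initialized transformer samples exactly on the
  lattice, where the sampler returns the input exactly.
* Gradient checks jitter all parameters slightly first: zero-initialized
  biases meet the transformer's exactly-zero border pixels, putting ReLU
  pre-activations exactly at the kink, where the analytic subgradient
  and central differences legitimately disagree.
* Max-pool ties route the gradient to the first maximum (deterministic);
  odd spatial sizes floor.
* Arg-max prediction ties resolve to the lowest level.
* `sigmoid` is computed branch-wise to avoid overflow on both tails.
* PCA sign is fixed by making each axis's largest-magnitude loading
  positive; degenerate (all-identical) feature sets are rejected.

## Known limitations

* No AU estimation from pixels: AU codings are inputs, as in the source
  archive protocol.
* Single images only — no temporal modeling.
* The softmax loss is unweighted; heavy class imbalance degrades the
  rare-class recall exactly as the reference results show (level 3
  recall 0%), and no imbalance-robust variant is provided.
* Thin-plate-spline or projective transforms, multi-transformer stacks
  and learned region proposals are out of scope; the transformer is a
  single full 2-D affine.
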