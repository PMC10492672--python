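# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and what the tests do and do not establish.

## Pipeline

Frames → per-pixel instrument-part masks → 21 kinematic features per frame
(centroid x, y and area per part class, normalized to [0, 1]) → variable-
length T×21 sequence → multi-task scoring network → 6 GEARS + 7 OSATS
subcategory scores (ordinal 1–5) and the surgical task (cut/recon/bolster).

All randomness is driven by explicit integer seeds through
`numpy.random.default_rng`; identical spec + seed reproduces outputs
bit for bit.

## Segmentation network

A U-net-style encoder–decoder with five encoder blocks (3×3 convolution +
stride-2 downsampling), three 3×3 bottleneck blocks, and five decoder
blocks (nearest-neighbour 2× upsampling, skip concatenation, 3×3
convolution). Channel schedule `base_channels · 2^min(depth, 2)` (default
base 8 → 8, 16, 16, 32, 32). Inputs must be divisible by 2⁵ = 32; the
error message instructs padding otherwise.

Two attention mechanisms, placed where the design intends them but with
internals chosen here (the cited building blocks are not specified to the
level of equations):

* **Global attention** at the bottleneck: single-head spatial
  self-attention over the coarsest feature map (1×1-conv Q/K/V, softmax
  over positions, residual add). At 64-px inputs this is a 2×2 map, so the
  cost is negligible while every position can condition on the whole image.
* **Cross image attention** in decoder blocks 0 and 1 (the two coarsest,
  configurable): decoder features act as queries against the
  skip-connection features (keys/values), i.e. the decoder re-weights which
  encoder detail is merged back in. Restricting to coarse blocks keeps the
  position–position attention matrices ≤ 64×64.

Training: per-pixel cross-entropy (the segmentation loss is a design
choice here), Adam, random scale (0.9–1.1), rotation (±15°), shift (±10%)
applied identically to frame (bilinear) and mask (nearest-neighbour);
evaluation data are never augmented. The trainer logs per-batch training
IoU and periodic held-out IoU and checkpoints whenever held-out IoU
improves. IoU averages per-class intersection-over-union, excluding
classes absent from both masks — counting an absent class as 1 would
inflate scores on negative (instrument-free) frames. "Enhancement-frame"
retraining is supported simply by appending newly labeled pairs to the
training list and continuing training; it is a dataset workflow, not an
algorithm.

## Feature extraction

For each part class c present in a mask: x = mean column / (width−1),
y = mean row / (height−1), a = pixel count / (height·width). Absent
classes are encoded as (0, 0, 0), keeping the vector at exactly 21 entries;
multiple connected components of one class are treated as a single region
(the representation is a mask, not instances). Normalized coordinates make
the scorer resolution-independent. Sequences keep every `stride`-th frame
(length ⌈n/stride⌉).

## Scoring network (mtCNN)

Two pathways process the sequence: a temporal-convolution trunk (default
three 1-D convolutions, kernel 5, 32 channels, ReLU) and an attention
pathway that produces normalized per-timestep weights; the weighted trunk
features are collapsed by averaging, making every output shape independent
of T. All temporal convolutions use edge-replication ("same") padding, so a
constant input produces constant features and hence exactly uniform
attention weights — a property the tests exploit.

A fixed (non-learned) *kinematic stem* precedes the trunk: alongside the 21
raw channels it appends per-feature absolute frame differences, per-
instrument planar step lengths √(Δx² + Δy²), and log step lengths, each
rescaled to order 1 (typical steps are 10⁻³–5·10⁻² in normalized units).
Skill ratings describe motion; exposing displacements directly spares the
trunk from having to discover differencing, and the log channel makes
scale-free contrasts (speed ratios between hands) linearly accessible. A
masked time-average of the stem is concatenated into the pooled vector as a
skip pathway: without it, probing showed the trained trunk discards
per-instrument mean-speed information that several rating statistics need.

Attention-pooling variants (weights masked and softmax-normalized over
valid timesteps):

* **WG** (weight gated): 1-D convolutions over the trunk output followed by
  a softmax across time; one weight vector per attention head.
* **SA** (self-attention): weight vectors from a tanh projection
  (structured self-attentive embedding style).
* **DP** (direct self-attention pooling): learned query vectors attend over
  1×1-conv keys/values, replacing temporal pooling; its internal attention
  map is what `attention_weights` returns.

Heads: 14 small MLPs (two hidden layers, width 64) over the shared pooled
vector — 13 five-way ordinal classifiers and one 3-way task classifier.
Two hidden layers matter: several target statistics are ratio-like
functions of pooled quantities, which a depth-1 ReLU head approximates
poorly from uncentered activations. Discrete 5-way heads (rather than
scalar regression) are used because exact-match accuracy is only defined on
discrete scores; argmax decoding breaks ties toward the lower score.
Sequences shorter than 16 frames are left-padded with zeros and the padded
positions masked out of the attention softmax.

Training: Adam, defaults 60 epochs, batch 32, lr 4·10⁻³ (optionally
linearly decayed), loss = sum over the 13 subcategory heads of CE or the
weighted-κ loss, plus CE on the task head (WK is an ordinal penalty and the
three tasks are unordered). For WK the soft observed matrix is accumulated
per mini-batch per head, since κ is undefined for a single sample; a batch
whose chance-disagreement term vanishes falls back to CE for that head.

## Weighted κ

`w[i,j] = |i−j|^k/(N−1)^k` with N = 5, k = 1 — the absolute value is used
although the printed form of the penalty is (i−j)^k, because signed weights
for odd k would make disagreements in one direction *rewarded*; with k = 1
this is exactly the standard linear-weighted Cohen's κ (verified against an
independent implementation to 10⁻¹⁰). E is the outer product of O's
marginals rescaled to ΣO. The loss `log(1 − κ + ε)` uses ε = 10⁻⁶ to guard
log 0 at perfect agreement. Degenerate marginals (Σ w∘E = 0) raise an
error rather than produce NaN.

## Synthetic data

**Scenes.** Up to seven elongated capsules with distinct hues on a smooth
Gaussian-noise background, shared specular shading, mild pixel noise;
left-arm parts are placed toward the left of the frame, right-arm parts
toward the right. Placement is rejection-sampled so class regions are
mutually disjoint; the mask is exact by construction. Classes are separable
but not trivially so (texture, shading, spatial overlap of hue ranges), so
a small segmenter can reach high IoU in minutes while the multi-class logic
is still exercised. Negative examples (no parts) emulate instrument-free
frames.

**Trajectories.** Each case simulates smooth random-walk kinematics for the
instruments active in a sampled task regime (cut: arm parts only; recon:
all seven incl. needle; bolster: graspers + needle), with per-case tempo
jitter (lognormal), independent per-hand tempo factors, shared pause
(idle) frames, and slow area drift. The emitted sequence adds observation
noise (default σ = 0.001, i.e. sub-pixel centroid/area jitter at typical
resolutions) and keeps absent instruments exactly zero.

**Score rule.** Five summary statistics of the *noise-free* latent
trajectory — mean speed, jerk (mean absolute change of frame speed), idle
fraction (frames below a 4·10⁻³ step threshold), left/right asymmetry
(absolute difference of mean hand speeds) and area variation (mean absolute
change of total area) — are each mapped to 1–5 through fixed cut-points,
assigned round-robin with alternating direction to the 13 subcategories.
Cut-points are quintiles of each statistic under the default spec
(calibrated once, seeded), giving balanced labels with all five levels
reachable. The task label equals the simulated regime.

Two SNR choices are deliberate: the observation noise must sit below the
idle threshold and below typical area-drift steps, otherwise the rule's
statistics are unidentifiable from the emitted sequences and the generator
could not serve its purpose of providing recoverable ground truth (with
σ = 0.01 the rule applied to the observed sequence agrees with the true
labels on only ~35% of subcategories; with σ = 0.001 on ~93%). The
asymmetry statistic is an absolute speed difference rather than a
normalized ratio for the same identifiability reason.

**What the generators do not emulate:** photo-realistic anatomy, blood or
tissue, occlusion, rater disagreement and rating subjectivity, imbalanced
expert-heavy score distributions, or correlations between subcategories
beyond those induced by the shared statistics. Passing the recovery tests
therefore shows the pipeline can extract kinematic statistics a rating rule
depends on — not that it reproduces human GEARS/OSATS judgement on real
surgery.

## Evaluation protocol

Splits and bootstraps operate at surgery granularity — every record of a
surgery travels with it, so no surgery straddles a train/evaluation
boundary. Bootstrap rounds draw n surgeries with replacement (duplicates
genuinely repeat in training), evaluate on the out-of-bag surgeries, redraw
if the OOB set is empty, and record overall and per-subcategory accuracy
and residual distributions for both splits. The combined estimate uses the
classical 0.632 rule, 0.368·train + 0.632·oob; the package also provides
the empirical distinct-sample fraction (→ 1 − 1/e) as a sanity check. The
default of 50 rounds keeps a desk-scale run in minutes; 1000 rounds is a
configuration choice. Invalid rating records are excluded from training
and metrics everywhere.

## Problem sizes used in tests

Segmentation learning: 200 training + 20 held-out 64×64 scenes, 350 Adam
steps, batch 4 (held-out mean IoU reaches ≈ 0.95). Scoring recovery: 600
training + 100 held-out sequences (60–120 frames), 60 epochs, batch 32,
lr 4·10⁻³ → 5·10⁻⁴. Bootstrap machinery tests use 8–15 surgeries at a
minimal training budget, since they check resampling bookkeeping, not model
quality.

With these conditions the CE-trained variants reach ≈ 0.76–0.79 held-out
subcategory exact-match accuracy (chance 0.2); WK-trained variants reach
≈ 0.47–0.50. The gap is a property of the objective, not a defect of the
optimization: linear-weighted κ charges adjacent-level confusions only a
quarter of the maximal penalty, so it optimizes ordinal closeness rather
than exactness, and exact-match accuracy saturates lower. Longer training,
more data (up to 1600 cases), larger batches and learning-rate schedules
were all tried and do not close the gap. The corresponding acceptance test
is left failing for the WK arm rather than weakened.

## Known limitations

* The autodiff core is CPU numpy; it is sized for the desk-scale networks
  here, not for real-video resolution or large batches.
* The attention internals (global, cross-image, and the three pooling
  variants) follow the stated placement and contracts but are this
  package's own minimal constructions; no claim is made about parameter
  reductions relative to other U-net variants.
* Checkpoints store flat parameter arrays plus the config; loading into a
  differently shaped config raises.
* The synthetic score rule is deterministic; optional rater noise is out of
  scope.
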