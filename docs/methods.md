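# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions the package implements, in enough detail to judge what the
tests do and do not establish.

## Problem setting

A smart mattress carries eight triaxial accelerometers (sites A–H: shoulder
blades A/B, spine C, coccyx D, hip–sacrum E/F, knees G/H) under the sleeper.
An FPGA front end polls the eight sensors round-robin at 240 Hz aggregate,
so each channel is sampled at 30 Hz; every read is three signed 16-bit axis
counts. Under a static posture each sensor reports a gravity-loading
projection, so the 8 × 3 static pattern is a posture signature. The
recognition task is six-way: prone, supine, left log, left fetus, right
log, right fetus. The acquisition protocol behind all default problem sizes
is 30 subjects × 6 postures × 25 windows = 4500 labeled windows.

## KNN-improved density-peak clustering (`somnipose.knn_dpc`)

Given points x_1..x_n with Euclidean distances d and diameter
σ = max d(x_α, x_β):

- **Local density** ρ_α = 1 − (1/k) Σ_{β ∈ KNN(α)} d(x_α, x_β)/σ, with
  k = 8 by default. ρ ∈ [0, 1] by construction; σ = 0 (all points
  coincident) is a degenerate-data error.
- **Repulsion factor** δ_α = min d(x_b, x_e) over x_b in the closed
  neighborhood KNN′(α) = KNN(α) ∪ {α} and x_e of *strictly* higher
  density. Every point attaining the maximum density takes
  δ = max_β d(x_peak, x_β) instead. Ties everywhere (distance and density)
  break by ascending point index, making the pipeline deterministic.
- **Centrality** γ_α = (ρ_α δ_α)^m with m = 2 by default.
- **Center selection.** Candidates are points with ρ above mean ρ *and*
  δ above mean δ (zero candidates is an error; one candidate means K = 1).
  Candidates are sorted by decreasing γ and adjacent gaps
  g_α = γ_α − γ_{α+1} are compared with their mean ḡ. K is set by the
  *boundary gap*: the largest α with g_α > ḡ, i.e. the first above-average
  gap met when scanning up from the weakest candidate. This is a deliberate
  reading of the gap rule: the strongest candidate is the global density
  peak, whose δ is the dataset diameter, so its γ always stands well above
  the rest and keying on the first above-average gap *from the top* would
  collapse K to 1 on essentially any data (we verified this on equidistant
  6-cluster benchmarks). The boundary gap instead separates the center
  group from the trailing noise candidates. If no gap strictly exceeds the
  mean (e.g. a single pair of identical centers), all candidates are kept,
  with a warning.
- **Assignment.** Non-center points, visited in decreasing density,
  inherit the label of their nearest strictly-denser point. A density peak
  that is not a center (possible only under density ties) attaches to its
  nearest center.

Properties the test suite enforces: exact agreement (discrete outputs) and
1e-12 relative agreement (continuous stages) with an independent
nested-loop reference on random instances n ≤ 30; ρ ∈ [0,1]; invariance of
K and labels under rigid motion and uniform scaling (δ scales linearly;
ρ is scale-free).

Default clustering features for posture windows are the 24 per-channel time
means. The role the original pipeline assigns to clustering relative to the
supervised stage is left open by its description; here clustering is an
independent stage, plus an optional *cluster-consistency filter*
(`pcsn.cluster_consistency_filter`) that drops windows whose cluster's
majority posture disagrees with their own label — explicitly an
interpretation, documented as such.

## Agreement metrics (`somnipose.cluster_eval`)

NMI(U,V) = 2·I(U,V)/(H(U)+H(V)) with entropies in nats (the base cancels);
0·log 0 := 0. If both partitions are single clusters (zero total entropy)
NMI is defined as 1 with a warning. ARI is the chance-corrected
pair-counting index computed from the contingency table with binomial
terms; when the adjustment denominator is zero (both partitions
all-singletons or both one cluster), the value is 1 if the tables coincide
and 0 otherwise, again with a warning. scikit-learn's implementations serve
as an independent cross-check in the tests, never as the implementation.

## PCSN classifier (`somnipose.pcsn`, engine in `somnipose._nn`)

Input: a window of T time steps × 24 channels (default T = 36 ≈ 1.2 s at
30 Hz, chosen so a 30 s posture hold yields the protocol's 25 windows).

- **Spatial path**: three parallel convolutional blocks. Each block is two
  temporal convolutions (channels 24→32→64, ReLU, 'same' padding) and the
  blocks differ by kernel size (3, 5, 7 samples), which is what makes the
  parallelism informative. Each block's feature sequence is summarized by
  global max pooling and global average pooling side by side (128 features
  per block).
- **Temporal path**: one LSTM and one Bi-LSTM over the raw window
  (hidden size 10 by default), each contributing final hidden state(s):
  10 + 20 features.
- **Fusion**: concatenation of the five branch outputs
  (3·128 + 10 + 20 = 414 features by default), one fully connected layer to
  6 logits, softmax.

Ablation variants built from the same blocks: `cnn` (spatial path only),
`cnn_lstm` and `cnn_bilstm` (serial conv stack feeding the recurrent cell).

Training: softmax cross-entropy, Adam (defaults: learning rate 1e-4, batch
size 64, maximum 400 epochs), stratified random 2/3–1/3 train/test split
(subject-wise holdout available as a stricter option). Precision, recall
and F1 are macro-averaged; classes are balanced by protocol so macro and
micro averages nearly coincide. Per-class ratios with empty denominators
count as 0. The engine is plain float64 numpy with hand-derived backward
passes (validated against central-difference gradients in the tests);
training with a fixed seed is bitwise-repeatable. The architecture
internals not fixed by the design brief (kernel sizes, channel counts,
pooling combination, which recurrent output is used) are the defaults
above, all exposed in `PCSNConfig`.

Problem sizes used by the automated checks are deliberately reduced from
the full 400-epoch schedule, because the synthetic task converges far
faster than real recordings: the held-out-accuracy check trains 8 epochs on
the full 4500-window dataset, and the ablation comparison uses
6 subjects × 10 sets (360 windows), 15 epochs, learning rate 1e-3, averaged
over 5 seeds. On this synthetic task all variants approach ceiling
accuracy, so the ablation check verifies the qualitative ordering
PCSN ≥ CNN+Bi-LSTM ≥ CNN+LSTM ≥ CNN within a 2-point tolerance rather than
a spread between variants.

## Synthetic study conditions (`somnipose.synthetic_data`)

The generator emulates the acquisition protocol, not body–mattress
mechanics. Each posture is a deterministic 8 × 3 loading template (units g,
entries within ±1.2 g): supine loads shoulder blades/coccyx/hips
vertically; prone shifts load toward spine and knees with a lateral
head-turn component at the shoulders; side postures carry a strong lateral
(y) component on the lying-side sensors; fetus variants unload the knee
sensors and shift weight toward coccyx/hips. Right-side templates are the
exact mirror of left-side ones (bilateral sensor rows swapped, y negated).
The `separation` parameter scales the posture-specific deviation from a
shared baseline; separation → 0 makes classes indistinguishable and is
rejected at 0.

A window is template × subject scale + per-subject sensor offsets
+ breathing sinusoid + per-window micro-shift + white noise, with defaults:

| parameter         | default | meaning                                        |
|-------------------|---------|------------------------------------------------|
| subject_scale_sd  | 0.07    | log-normal loading scale (anthropometric)      |
| sensor_shift_sd   | 0.02 g  | per-subject per-sensor static offsets          |
| breathing_amp     | 0.02 g  | chest-wall modulation, torso sensors A–F, z    |
| breathing_freq    | 0.25 Hz | resting respiratory rate (~15 breaths/min)     |
| micro_shift_sd    | 0.05 g  | per-window positional adjustment               |
| noise_sd          | 0.03 g  | white sensor noise per sample                  |

The micro-shift default is deliberately of the same order as the
between-subject variation: the protocol *instructs* participants to make
small positional adjustments between windows precisely to diversify each
posture's data, so within-class variation is unimodal rather than split
into per-subject clumps. The published study reports no raw signal
statistics, so all of these scales are the package's own choices, exposed
in `GeneratorConfig`.

What the generator does **not** model — and therefore what passing tests do
not show about real recordings: mattress-material transfer functions,
body-shape-dependent loading geometry beyond a scalar scale, movement
artifacts and posture transitions, co-sleepers, long-range drift. Accuracy
figures measured on this synthetic task are parameter-recovery results
under the stated conditions, not reproductions of the published accuracy on
real recordings (whose data is available only on request).

The rotating-rig simulation reproduces the sensor evaluation: readings at
5° increments over 0–180°, ideal response g·cos θ, per-sensor gain/offset
errors and read noise configurable. The consistency check is a one-way
ANOVA with sensor identity as the factor over residuals from the ideal
cosine — residuals rather than raw readings so that angle is not a
confounder. Under identical sensors the rejection rate at α = 0.05 is the
nominal 5% (type-I control, checked over 200 sweeps); an injected gross
offset on one sensor is detected with high power.

## Stream dialect (`somnipose.stream_io`)

The published description fixes the payload (48 bits = three int16 axis
values per sensor read, eight sensors polled round-robin, UART at
115 200 bps) but not the on-wire framing, so the module defines its own
self-consistent dialect — sync `0xAA 0x55`, sensor-index byte, little-endian
payload — and ships both encoder and decoder; round-trip identity and
resynchronization after corruption are tested. The default count-to-g
scale, 3.9 mg/LSB, is the named accelerometer's full-resolution
sensitivity; it is configurable.

## Seeds and reproducibility

Every stochastic stage takes an explicit integer seed and uses
`numpy.random.Generator`. The CLI derives per-stage 31-bit seeds from the
global `--seed` via `SeedSequence([seed, stage_index])`, so individual
stages can be reproduced in isolation; reports embed a configuration hash.

## Known limitations

- The synthetic task is much easier than real recordings; classifier
  accuracies near 100% on it indicate correctness of the implementation,
  not expected field performance.
- The boundary-gap reading of the cluster-count rule is our resolution of
  an ambiguous description (see above); both readings coincide on the
  geometric-sequence worked example but differ on data where the top
  centrality stands alone.
- The published headline metrics (98.42% accuracy etc.) were obtained on
  recordings that are not publicly distributed and are therefore not
  reproduced here.
- The stream dialect's framing is artifact-defined; hardware captures from
  the original front end would require adapting sync handling.
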