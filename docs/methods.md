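# Methods

## Overview

`soconvesn` classifies skeleton action sequences with an echo state
network (ESN) whose fixed weights are *learned*, not drawn at random.
The pipeline has two components:

1. **Self-organizing reservoir construction.**  Each of five body-part
   channels (left/right arm, central trunk, left/right leg; a `T x 9`
   series of three joints' xyz coordinates) trains its own
   self-organizing network that combines an ART-style vigilance test
   with ITM-style topology learning.  The resulting node centroids `C`
   (K x 9) and binary interconnectivity `E` (K x K) deterministically
   initialize the ESN: `Win` is `C` affinely rescaled into
   `[-IS, +IS]`, and `Wres = (SR / λmax(E)) · E`, so the recurrent
   matrix has spectral radius exactly `SR`.  Driving the reservoir with
   a channel series through `x(t+1) = tanh(Wres x(t) + Win u(t+1))`,
   `x(0) = 0`, yields the echo state representation (ESR), a `T x N`
   state matrix.  Because every step is deterministic, the whole chain
   reproduces bit-identically under one seed — the property that
   motivates self-organized initialization over random draws.

2. **Multiscale convolutional readout.**  The five ESRs feed three
   convolution blocks — trunk alone, left+right arm stacked as two
   input channels, left+right leg likewise — with full-height filters
   of time scales k ∈ {2, 3, 4}, ReLU, and max-over-time pooling.
   Pooled scalars are concatenated and a single fully connected layer
   produces softmax class probabilities; training minimises
   cross-entropy with Adam.

Reservoir hyperparameters are tuned by recurrence quantification
analysis (RQA) of the ESR rather than by rule of thumb: the recurrence
plot `R[i,j] = Θ(τ − ‖x_i − x_j‖)` is summarized by LMAX (longest
diagonal line — stability), DET (determinism), LAM (laminarity) and RR
(recurrence rate), and a two-stage sweep selects input scaling and
spectral radius by maximizing LMAX under the echo-state-property cap
`SR ≤ 0.99`.

## Self-organizing learning rules

Each frame is perturbed before learning, `z(t) = u(t) + s·t^(−2η)·1`,
a deterministic, time-fading offset that breaks early symmetry and
accelerates convergence of the clustering.  Defaults `s = 0.1`,
`η = 1`; `s = 0` disables it.  The printed form of this perturbation in
the originating description is internally inconsistent (an "identity
matrix" added to a vector, no scale); the implementation uses the only
reading compatible with a tunable scale and decay over time.

One learning step:

* **Matching.**  Nodes are ranked by Euclidean distance to `z`.  The
  nearest node passing the vigilance test `d ≤ V` becomes the winner
  `b` (candidates are tried in ascending distance; ties break to the
  lowest index).
* **Update.**  `w_b ← w_b + ε_b (z − w_b)` — an exact contraction:
  the winner's distance to `z` shrinks by the factor `(1 − ε_b)`.
* **Topology.**  If the second-best node `s` also passes the test, the
  edge `(b, s)` is created, and every neighbour `n` of `b` with
  `d(w_b, w_s) ≤ d(w_b, w_n)` loses its edge to `b`.  Edges carry no
  age; the deletion rule alone keeps the graph local.
* **Insertion.**  If every node fails the test, `z` becomes a new
  node.  In a non-empty network the new node is linked by an edge to
  its best match — the classical ITM insertion convention.  Without
  this link, periodic pruning (below) at short cycles would delete
  every fresh node before it could ever acquire an edge, and the
  network could not grow at all.
* **Pruning.**  Every `λ` steps (default `⌈0.1·N_max⌉`), edgeless
  nodes are removed, least-recently-used first; a lone node is kept.

**Capacity and stopping.**  `N_max` (the reservoir size `N`) caps
growth.  For 9-feature channels, `N ≥ 3 × 9 = 27` gives the reservoir
enough state dimensions in practice, and 27 is the default.  Once the
cap is reached, insertion stops but winner updates, edge adaptation and
pruning continue to the end of that epoch, so the remaining frames
still shape the centroids; fitting returns after that epoch (or after
`max_epochs = 10` passes if the cap is never reached, with a warning).
Stopping instantly at the cap was considered and rejected: it leaves
centroids equal to raw early samples and makes cluster recovery depend
strongly on stream order (in the four-cluster recovery experiment
below it failed for about half of the random orderings, versus ~15%
for the continued-epoch rule; the residual failures are inherent to
capacity-capped competitive learning without node recycling, which
this method does not include).

Defaults follow the regime in which the method was developed:
`V = 0.05` (low vigilance, fine-grained clusters), `ε_b = 0.5`,
`s = 0.1`.  All are configuration.

## Recurrence analysis conventions

* Θ(0) = 1: a pair exactly at the threshold is a recurrence, matching
  the inclusive vigilance convention.
* The line of identity (main diagonal) is excluded from the diagonal
  histogram by default; otherwise LMAX would trivially equal `T`.  A
  flag restores the literal reading.
* `lmin = vmin = 2` by default (the standard RQA choice).  Note a
  finite all-ones plot has two corner diagonals of length 1, so DET at
  `lmin = 2` equals `1 − 2/(T² − T)`, not exactly 1; total determinism
  is exact only at `lmin = 1`.
* Default threshold `τ = 0.1 ×` the maximum pairwise state distance.
* Recurrence plots are `O(T²)`; computation is blockwise and refuses
  `T > 5000`.  Tuning sweeps run on the concatenation of a channel's
  training series truncated to `max_frames` (default 400 in the
  pipeline, 1000 in the tuner API) to bound this cost.

## Two-stage tuning

Stage 1 fixes `SR = 0.99` (the boundary value conventionally taken to
guarantee the echo state property) and sweeps IS over a log-spaced grid
in `[0.07, 0.5]`; stage 2 fixes the chosen IS and sweeps
`SR ∈ {0.5, 0.8, 0.9, 0.99, 1.1, 1.5, 2.0}`.  LMAX is reported for the
whole grid — including `SR > 1`, where the ESP is violated, for
diagnosis — but selection is restricted to `SR ≤ 0.99`.  Ties in LMAX
break to the **largest** admissible parameter (the top of the stable
plateau).  Sweeps are pure functions of their inputs and replay
bit-identically.

## Readout and training

Valid (no-padding) correlation along time: a `k × N` filter over a
`T x N` ESR yields `T − k + 1` positions.  Dual-channel filters span
the horizontally stacked left and right ESRs.  One fully connected
layer maps the pooled feature vector (3 blocks × |scales| × F entries)
straight to class logits — no hidden dense layer or dropout, the
simplest readout consistent with the architecture.  Weights are
initialized with a seeded uniform Glorot-style fan-based scheme; Adam
uses β₁ = 0.9, β₂ = 0.999, ε = 1e−8.  Forward, backprop and Adam are
implemented directly on numpy, which keeps training exactly
reproducible under a seed.  Training is resumable (optimizer state is
retained), which the resource-based hyperparameter searches rely on.
If channel reservoirs end at different sizes after pruning, the conv
blocks simply take their actual input widths.

## Hyperparameter search

The search space covers number of filters (discrete), learning rate
(continuous, log-scaled) and batch size (discrete); the objective is
validation accuracy and must be deterministic given (config, resource,
seed), with training epochs as the resource unit.

* **BO** — Gaussian-process surrogate (Matérn 5/2), expected
  improvement acquisition maximized over random candidate draws;
  2 random warm-up points per run; 5 evaluations per run over
  independent restarts.
* **ASHA** — rungs `r·η^i` up to `R_max` (defaults η = 4, r = 1,
  R_max = 64, early-stop rate 0 ⇒ rungs 1, 4, 16, 64).  A trial is
  promotable when its rank among completed trials at its rung is below
  `n/η` — so eight completed trials promote exactly their top quarter,
  and a lone trial advances unimpeded.  Workers are simulated
  sequentially; decisions use only results already available.
* **PBT** — population 10, five generations, truncation selection:
  the bottom 20% copy a uniformly drawn top-20% member's configuration
  (ties keep incumbents) and perturb the learning rate by ×0.8 or
  ×1.2.  The filter count is never perturbed, since changing the
  architecture would void inherited weights.

Failed objective evaluations are recorded on their trial and the
search continues.  All searches replay exactly from (seed, config).

## Synthetic data

The generator emulates what distinguishes skeleton action classes:
which limbs move, how fast and how far.  Each class is a set of
per-part sinusoids (frequency in cycles/frame, amplitude, phase)
around a fixed standing rest pose, with distal joints moving more than
proximal ones and xyz phases staggered; Gaussian jitter
(σ = 0.02, about 2% of limb amplitude — Kinect-like) and uniformly
drawn lengths (30–40 frames, matching the tens-of-frames regime of
real captures) complete a sample, zero-padded to the batch maximum.
The four default classes (arm waving, marching, trunk bending, whole
body bouncing) occupy disjoint frequency/limb-usage bands and are
1-NN-separable on raw series — so end-to-end tests certify the
pipeline's mechanics, not representation learning on hard data.  The
generator does not model: inter-subject skeleton-scale variation,
aperiodic or transient motions, occlusion artifacts, or sensor
drop-out; results on it say nothing about recognition accuracy on real
benchmark captures.

A second generator produces seeded isotropic Gaussian mixtures for
clustering parameter-recovery experiments.

## Numerical and degenerate-input choices

* Distance ties in matching break to the lowest node index.
* Constant centroids (max = min) cannot be rescaled — an error.
* An edgeless interconnectivity matrix has zero spectral radius and
  cannot be rescaled — an error.
* Empty RQA histograms yield metric 0 with a warning.
* `x(0) = 0` for all ESR computations (any fixed choice works under
  the ESP; zero is the reproducible convention).
* One global pipeline seed derives all stage seeds via
  `numpy.random.SeedSequence`; every derived seed is reduced below
  2³¹.

## Problem sizes used in tests and the acceptance script

The synthetic study runs 4 classes × 40 samples (T ≤ 40, five 9-dim
channels), reservoirs of N = 27, readout with 16 filters per scale and
kernels {2, 3, 4}, 30 training epochs, tuning on ≤ 400 concatenated
frames; oracle probes use 200 random recurrence plots (T ≤ 30), 100
random convolution instances, and an 800-point four-centre mixture.
These sizes are the package's chosen study conditions and complete in
a few seconds on one CPU core.

## Known limitations

* Capacity-capped competitive learning can leave a cluster
  unrepresented when the stream order fills the network before that
  cluster appears (~15% of orderings in the four-cluster recovery
  setting); the method has no node-recycling mechanism to correct
  this.
* LMAX saturates near its maximum on strongly periodic input, which
  flattens the tuning landscape; the largest-parameter tie-break then
  effectively selects the top of the grid.
* The readout trains full-batch-per-minibatch on dense ESR tensors in
  memory; it targets datasets of hundreds to thousands of sequences,
  not GPU-scale corpora.
* Only tanh (and identity, for testing) activations are provided.
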