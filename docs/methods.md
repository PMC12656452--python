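# Methods

This note records the modelling conventions, parameter choices and numerical
decisions behind `pflnet`, and what the desk-scale experiments do and do not
demonstrate.

## Model

The classifier taps the last three stages of a staged convolutional
backbone. The backbone is a contract — an ordered list of stages, each
mapping the previous output to a `C×H×W` feature map — and the package ships
`TinyBackbone`, a narrow 3-stage CNN (stride-2 convolutions with group
normalisation; 96 px inputs give 24/12/6-cell grids). Any richer backbone
honouring the contract (e.g. a ResNet-style network) can be plugged in; none
is required.

Each tapped map `F_n` passes a stage pipeline:

1. **Refinement** `V_n = relu(GN(conv1×1(F_n)))` — the feature the polar
   head reads and all later consumers share.
2. **Projection** to a common channel width (default 32) so all scales can
   be fused.
3. **Fusion** across scales (MCPM), **global average pooling**, and a
   two-layer classifier head per stage plus one head on the concatenation
   of all pooled stage features (four heads total).

### Polar-coordinate refinement (SSRM)

* Grid coordinates are 0-based, row-major; `(x, y)` is (row, column).
* Targets: `r_ij = sqrt((x−i)² + (y−j)²) / (N√2)` — normalised by the grid
  diagonal so `r ∈ [0, 1]` — and `θ_ij = (atan2(y−j, x−i) + π) / 2π`
  wrapped into `[0, 1)`. The reference cell carries `r = 0` and, by
  convention for the indeterminate `atan2(0, 0)`, `θ = 0`; since its radial
  target is exactly zero this convention is benign.
* The object mask is the rectified channel mean of the backbone stage
  feature, min–max normalised; a constant map falls back to the uniform
  mask. The mask weights the losses but is detached — it receives no
  gradient. (The alternative, letting the mask branch learn through the
  losses, is unexplored here; nothing in the loss formulation requires it.)
* The reference cell is the mask argmax with ties broken by smallest row,
  then smallest column — determinism matters more than the tie itself.
* The prediction head is a single affine map shared by all cells, applied
  to the concatenation of the cell's and the reference cell's feature
  columns, squashed by a logistic sigmoid to match the `[0, 1]` targets.
* `L_d` is the mask-weighted mean squared radial error; `L_a` is the
  mask-weighted **variance** of the wrapped angle error. Exact invariances
  (tested): positive mask scaling; co-rotation of predicted and true
  angles; a prediction equal to the target plus any constant offset scores
  zero. Note the variance is *not* invariant to adding an arbitrary
  constant to an arbitrary prediction when the wrap boundary is crossed
  unevenly across cells; the invariance that motivates the design is the
  co-rotation one.
* Per-batch, per-stage losses are summed over images (matching the
  per-image definitions); the training objective scales the sum by
  `1/batch` so the term's weight does not grow with batch size.

### Cross-scale fusion (MCPM)

`M = X₁ᵀX₂` over pixel columns; attentions are column-wise softmaxes of the
*negated* similarities — the printed form "−softmax(M)" cannot lie in
`[0, 1]`, and negating the argument is the only reading consistent with both
the stated range and the semantics that *low* similarity means *high*
complementarity. Every fused pixel is therefore a convex combination of
source pixels dominated by the least redundant ones. Fusion strength
`γ = 2`. The module is parameter-free; channel projections live in the
network. The batched code path is exactly the per-image math (tested to
float precision).

### Channel decoupling (CD)

The final refined stage is projected to `c·k` channels (`k = 2` per class
by default; small `k` keeps the projection narrow for large class counts). Class `i` owns the contiguous
channels `[ik, ik+k)`. Scores use an element-wise uniform `[0, 1]` random
mask (resampled per evaluation from the seeded training generator), a
per-location maximum over the first `ξ` masked channels (`ξ = k` by
default; `ξ` is exposed in the config), then a spatial mean;
cross-entropy over the softmaxed scores is weighted by `μ = 0.3` in the
total objective. Whether the mask multiplies element-wise or per-channel is
an open reading; element-wise is implemented.

### Objective and optimisation

`L = Σ₄ L_CE + μ·L_CD + (λ/B)·Σ L_ssrm`, with λ = 1 and all four heads
weighted equally (the concatenation head participates in training). SGD
with momentum 0.9, weight decay 5e-4; backbone and new layers follow
per-step cosine annealing, the concatenation head (the "auxiliary"
classifier) keeps a constant rate. A global L2 gradient clip (default 5.0)
guards the normalisation-light tiny backbone against early divergence.
Inference averages the softmax of all four heads (a config switch selects
the concatenation head alone); ties resolve to the smallest class index.

## Full-scale vs desk-scale configuration

`PFLConfig` defaults describe the full-scale recipe (448 px inputs,
lr 2e-4 backbone / 2e-3 new layers / 1e-2 auxiliary, 200 epochs) which
presumes a large pretrained backbone. `desk_config` is the CPU-sized
variant used by the tests and the acceptance script: 96 px inputs, the
tiny backbone trained from scratch, lr 0.02 (cosine) for 15 epochs, batch
32, augmentation = reflect-pad random crop + horizontal flip. These sizes
were chosen as the smallest configuration on which the easy benchmark
saturates.

## Synthetic specimen benchmark

The generator emulates the structure of standardised specimen photography:
a centred elongated larval body on a noisy near-black background, four
discrete capture poses (back / foot / left / right as flips and rotations),
and six part features with class-controlled geometry — dorsal ring count,
head size, eye separation, leg spacing, body curvature, body hue. A class
is one fixed parameter vector; within-class variation is seeded jitter
(translation, small rotation, brightness, pixel noise). Datasets are
balanced, with a seeded 70/30 per-class split.

* **easy** preset: six classes differing in *every* attribute including
  hue, no rotation jitter. Largely colour-separable by design — a sanity
  benchmark the full model should saturate (≥95% is asserted; 100% is
  typical).
* **hard** preset: one shared hue, so discrimination must rely on geometry
  under rotation/shift/photometric jitter. Baselines land mid-range
  (roughly 40–90% across seeds), leaving headroom for component effects.

What passing these benchmarks shows: the losses are wired correctly, the
model trains stably end-to-end, and the pipeline can exploit both colour
and shape cues. What it does not show: performance on real photographs —
the generator has no texture, no illumination field, no occlusion, no
device variation, and its class boundaries are axis-aligned in a small
parameter space.

## Desk-scale ablation: honest readout

With the frozen desk conditions (hard preset, batch 32, 15 epochs, seeds
0/1/2) the median test top-1 of the full model (50.0%) exceeds the
multi-head CE baseline (41.1%), matching the expected direction. Wider
seed sweeps show this regime is noise-dominated: run-to-run spread spans
tens of points, and per-component medians at batch 16 rank MCPM clearly
positive, CD roughly neutral, SSRM negative. The SSRM result is expected
from scratch: its reference cell is the argmax of an untrained feature
mask, i.e. noise at initialisation, so early polar supervision is
uninformative — with a pretrained backbone the mask is meaningful from the
first step. Desk-scale ablations here are directional smoke tests, not
effect-size estimates.

## Numerical choices and degenerate inputs

* All-zero or constant feature maps yield the uniform object mask; an
  all-zero mask passed directly to a loss is rejected.
* Angle wrap: `θΔ = θ′ − θ` plus 1 where negative; the wrap indicator is
  treated as a constant under differentiation (the discontinuity has
  measure zero).
* Softmaxes subtract a detached per-column maximum for stability; `max`
  distributes gradient equally over exact ties.
* Seeding: every run derives all generators (init, shuffling, augmentation,
  CD masks) from the config seed via `SeedSequence`; repeat runs are
  bit-identical, and the batched CD mask draw consumes the generator in
  the same order as the per-image loop, so both paths agree exactly.
* float32 is used throughout training; the loss-module APIs preserve the
  caller's dtype (tests use float64 against float64 oracles).

## Limitations

* No pretrained backbone is bundled; results on real imagery are untested.
* The ablation noise above: 15-epoch from-scratch runs are not the regime
  in which the refinement and decoupling losses were designed to shine.
* The autodiff core implements exactly the primitives this model needs; it
  is not a general framework (no broadcasting matmul beyond batch dims, no
  in-place ops, CPU only).
* `k`, `ξ`, λ and the mask construction are exposed in the config but only
  their defaults are exercised by the acceptance experiments.
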