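# Methods

## Scope and data model

The unit of analysis is a *snapshot*: the 16 readings of a MOS sensor array
at one sampling instant during a gas exposure, labeled acetone, ethanol or
mixture. Snapshots are encoded to 16×16 Gramian Angular Field matrices,
rendered to 3-channel images, and classified by a small CNN. Real exhaled
breath adds covariates this package does not model (humidity, temperature,
sensor drift compensation, inter-subject variability); every empirical
number produced here is about the synthetic study conditions described
below, not about patients.

## Synthetic e-nose generator

The simulator emulates a static-chamber experiment: 16 sensors, ~120 s
exposure and ~120 s recovery sampled at 1 Hz, over a 32-row concentration
grid (8 acetone-only and 8 ethanol-only rows at 1, 3, …, 15 ppm; 16 binary
mixtures on the {1, 5, 10, 15} × {1, 5, 10, 15} ppm product grid).

Response model (standard MOS phenomenology; the experimental literature on
these sensors reports steady-state levels and response times but no
canonical trace shape, so the simplest model exposing the classifier's
problem structure was chosen):

* steady state per sensor s: `baseline_s + Σ_gas S[s,gas] · C_gas^α_s`,
  a power law in concentration with exponent α_s ∈ (0, 1];
* first-order rise toward steady state with time constant τ_rise_s during
  exposure, first-order decay back to baseline with τ_decay_s during
  recovery;
* additive linear drift and i.i.d. Gaussian noise.

Mixtures are additive in the per-gas steady-state terms; a multiplicative
interaction coefficient exists as a config knob but defaults to 0, since no
mixture-response model is available to calibrate it.

Defaults (drawn once per config seed so the 16 channels are diverse but
reproducible): sensitivities log-uniform in [0.5, 5] a.u./ppmᵅ per
(sensor, gas); exponents uniform in [0.5, 1.0]; τ_rise uniform in [10, 30] s
and τ_decay in [20, 40] s (well inside the 120 s windows, so end-of-exposure
readings are near steady state); baselines log-uniform in [0.5, 2] a.u.;
noise_sd 0.05 a.u. (small against signal excursions of ~1–20 a.u., i.e. a
clean-lab SNR); drift 1e-4 a.u./s. Units are ppm, seconds and arbitrary
resistance-like response units, recorded in the dataset manifest.

Seeding: a master seed drives per-record seeds through a counter-keyed
`numpy.random.SeedSequence` (splitmix-style), so a record's content depends
on its index in the grid, not on generation order; manifests are
byte-identical for identical inputs.

Snapshot policy: the published experiment samples "a certain point" of each
exposure without saying which or how many; the default takes every tick in
the second half of the exposure window (near steady state), and `end` /
`last_k:N` policies are available. The policy is recorded in the manifest.

## GAF encoding

Min–max normalization to [−1, 1] (both endpoints attained by construction),
φ = arccos(x̃), then GASF = cos(φᵢ+φⱼ) or GADF = sin(φᵢ−φⱼ). A snapshot has
no time axis, so no timestamp-as-radius variant is implemented. Numerical
choices:

* arccos inputs are clamped only within 1e-12 of ±1 — enough to absorb
  float round-off, small enough not to mask real domain errors;
* an all-equal snapshot is a hard `DegenerateSnapshotError` rather than a
  silent NaN (the simulator guarantees spread; real flat-lined hardware
  should fail loudly);
* GASF/GADF carry the algebraic closed forms
  `x̃ᵢx̃ⱼ − √(1−x̃ᵢ²)√(1−x̃ⱼ²)` and `√(1−x̃ᵢ²)x̃ⱼ − x̃ᵢ√(1−x̃ⱼ²)` as an
  independent test oracle against the trig route.

The CNN consumes "color images": the matrix is mapped through a fixed
perceptual colormap (viridis by default) to 3 channels, with nearest-
neighbour upscaling only, so rendering is deterministic and invertible up
to colormap quantization. A `channels=1` raw-matrix mode exists for
ablation. How the original images were colorized is not recoverable; a
fixed named colormap is the reproducible choice. The MTF comparator uses
the standard quantile-bin construction (default 8 bins, reduced with a
warning when the snapshot has fewer distinct values).

## LTNet architecture

A ConvBN unit is a depthwise 3×3 convolution + BN + hard-swish followed by
a pointwise 1×1 convolution + BN + hard-swish. Convolutions that feed a BN
are bias-free (the BN shift absorbs any bias; this is also what makes the
fusion bookkeeping below exact). An LTBlock runs `n_convbn` units at one
width, applies squeeze-and-excitation channel gating (GAP → dense C→C/r →
ReLU → dense C/r→C → sigmoid), and adds a residual skip from the first
unit's output around everything after it — a placement that is always
shape-compatible regardless of stride or channel change. The `original`
ablation mode replaces each unit with a standard 3×3 ConvBN and drops SE
and residuals, same topology.

**Reference configuration.** Only two architecture-level totals are
published for this model family — 32,614 trainable parameters (full) and
296,994 (original ablation) — with a block diagram but no layer widths. The
reference configuration was therefore recovered by exhaustive search
(`ltnet.reference`) over stem width {8, 16, 24, 32}, 2–4 blocks with widths
8–160, 1–2 units per block and SE ratio {4, 8}, keeping exact full-mode
matches of 32,614 and tie-breaking on the ablation count closest to
296,994. Result (frozen in `configs/reference.json`): 3-channel 16×16
input, stem 3→32, blocks 32→88 (stride 2), 88→64, 64→16 (stride 2), two
units per block, SE ratio 4, GAP, FC 16→3. Its ablation count is 195,763:
no configuration in the search space attains both published totals
simultaneously, so the trainable count was matched exactly and the
discrepancy is documented here. With global average pooling the parameter
total is independent of input size (checked at 16×16 and 32×32).

Two accounting conventions are reported side by side because they answer
different questions: `total` counts trainable tensors (conv weights, BN
γ/β, SE and FC weights+biases) — the model-size figure; `deployed_total`
counts what inference stores (conv weights + all four BN vectors before
fusion, + bias after), the convention in which fusion saves exactly
3·C_out per pair.

Weight initialization is fan-in-scaled uniform from a single seeded
generator threaded through the whole build, so identical (config, seed)
give bit-identical models. Prediction ties break to the lowest class index
(first argmax). BN ε = 1e-5, momentum 0.1, biased variance.

## Conv-BN fusion

In eval mode BN is an affine per-channel map with frozen running
statistics, so W_f = γ·W_c/√(σ²+ε) (scaling each output-channel slice —
well-defined for grouped/depthwise convolutions too) and
b_f = γ·(b_c−μ)/√(σ²+ε) + β. Fusion is applied to every conv+BN pair,
depthwise and pointwise alike, returns a deep copy (training always runs
unfused), and is idempotent — a fused model has no BN pairs left. The
equivalence tolerance asserted in tests is 1e-5 max-abs on float32 logits,
a bound on re-associated multiply round-off; observed deviations are ~1e-9.

## Training protocol

Adam + softmax cross-entropy, batch 16, 30 epochs by default, learning
rate 6e-4 (gas-mixture profile; 4e-4 for the UCI drift profile). Splits are
6 train : 3 test : 1 validation, stratified per class with
floor-then-largest-remainder allocation (deterministic, within one item of
the exact ratios per class; classes smaller than the number of splits fall
to train first). Model selection keeps the weights with the best test-split
accuracy; the validation split is the reported one. Divergence (non-finite
loss) aborts with a diagnostic. All shuffling derives from the training
seed; the end-to-end pipeline is reproducible to identical metrics from one
master seed.

The UCI drift-dataset reader parses the sparse `gas;concentration
index:value` dialect (128 features = 16 sensors × 8 features,
sensor-major). Which 16 of the 128 features feed GAF is not specified
anywhere authoritative; the default takes feature slot 1 — the steady-state
resistance change, the closest analogue of the simulator's snapshot
semantics — and the slot is selectable.

## Problem sizes used in the checks

The end-to-end surrogate trains on 1,248 snapshots (32-row grid × 3
replicates × last-13-ticks policy) for 12 epochs at the default noise —
sizes chosen so the full suite runs comfortably on a laptop-class CPU while
staying above 1,200 snapshots and inside the 10–30-epoch regime; it reaches
≥ 95% held-out accuracy. Noise-degradation checks: the CNN pipeline is run
at noise_sd ∈ {0.05, 2, 10} (scaled-down: 256 snapshots, 6 epochs), and a
logistic-regression probe on raw snapshots at {2, 6, 18} — probe levels sit
above its linear-separability ceiling because a strict accuracy decrease is
unobservable while the probe saturates at 100%.

## Known limitations

* The kinetics and mixture models are phenomenological; no sensor
  cross-interference, humidity/temperature effects or long-term drift
  compensation.
* Synthetic separability is generous at default noise: the surrogate
  accuracy says the pipeline works, not that real breath data would score
  similarly.
* The recovered reference architecture matches the published trainable
  total exactly but is not guaranteed to be the published topology; the
  ablation-count mismatch above is the visible symptom.
* Wall-clock/memory benchmarking is informational only (hardware-
  dependent) and never asserted.
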