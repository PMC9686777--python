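# Methods

## Problem and signal model

Field recordings of birdsong routinely contain several birds vocalizing at
once. `birdsep` addresses the supervised, single-channel, two-source case:
a mono mixture

    x(t) = s1(t) + α · s2(t),        α = sqrt( Σ s1² / (10^(q/10) · Σ s2²) ),

where q (dB) is the relative level imposed between the sources, optionally
plus background noise injected at a controlled SNR. The network estimates
ŝ1, ŝ2 from x alone. C = 2 is fixed; an unknown source count is out of
scope.

## Architecture

The separator follows the time-domain encoder–separator–decoder design:

1. **Encoder** — bias-free 1-D convolution (kernel 16, stride 8, N = 256
   filters) followed by ReLU: a learned, non-negative STFT surrogate
   mapping T samples to a feature w ∈ R^(N×L), L = ⌊(T−16)/8⌋ + 1.
2. **Bottleneck** — channel layer norm then a 1×1 convolution N → d.
   The separator width d = 72 is a calibrated value (below).
3. **Segmentation** — the (d, L) feature is cut into S chunks of length
   K = 120 with 50% overlap (hop P = 60). A front pad of P and a tail pad
   aligning the total to a multiple of P guarantee every original frame is
   covered by exactly two chunks, so overlap-add (sum, halve, strip pads)
   inverts segmentation exactly.
4. **Dual-path core** — B = 6 repetitions of an intra-chunk pass (the block
   applied to each chunk, sequence length K) followed by an inter-chunk
   pass (the block applied across chunks at each within-chunk position,
   sequence length S). No weights are shared between the 2B blocks.
5. **Tiny-transformer block** — instead of positional encodings and a
   feed-forward network, a strided depthwise convolution (kernel TCK = 4,
   stride TCS = 2) sits in front of multi-head self-attention, halving the
   sequence (attention cost drops to a quarter) while mixing local position
   information; a depthwise transposed convolution restores the length:

       Z   = conv1d(X)                       # (d, M) -> (d, ceil(M/2))
       Mid = LN(Z + MultiHead(Z))            # h = 4 heads, scaled dot-product
       Y   = conv1d_transpose(ReLU(Mid))     # back to (d, M)

   The single residual sits inside the layer norm; there is no second
   residual around the deconvolution and no dropout.
6. **Mask head** — a 1×1 convolution maps d → C·d channels; per source the
   d-channel slab is overlap-added back to (d, L), passed through a gated
   output stage (tanh(conv) ⊙ sigmoid(conv), the dual-path-RNN lineage
   convention), then a 1×1 convolution d → N and ReLU produce the
   non-negative mask mᵢ ∈ R^(N×L).
7. **Decoder** — ŝᵢ = ConvTranspose1D(w ⊙ mᵢ), bias-free, same kernel and
   stride as the encoder, output trimmed/padded to T.

### Calibrating the unpublished separator width

The published description fixes kernel/stride/N/K/B/h/TCK/TCS but never
states the width at which the dual-path core runs, while reporting 0.4 M
parameters and 2.943 / 5.893 / 11.651 GFLOPs for 4-second inputs at
8 / 16 / 32 kHz — figures a 256-wide core exceeds by an order of magnitude,
so a bottleneck must exist. We swept d (multiples of the head count) against
three conv styles for the block's front/restore pair (full, depthwise,
depthwise-separable), an optional gated output stage, and the counting
convention axes (1 or 2 FLOPs per multiply-accumulate; attention matrix
products in or out; bias adds in or out). Selected configurations:

| style     | gated | d   | params    | max FLOPs err |
|-----------|-------|-----|-----------|---------------|
| depthwise | yes   | 72  | 355,248   | 0.66%         |
| depthwise | no    | 76  | 367,480   | 4.5%          |
| full      | no    | 48  | 384,864   | 7.9%          |

The winner — depthwise convs, gated output, **d = 72**, MAC = 2 FLOPs,
attention matmuls and elementwise ops excluded — reproduces 0.4 M and
2.962 / 5.907 / 11.718 G (all within 0.7%), with the 16→32 kHz ratio 1.98
("almost doubled"). It is frozen as the package default; the convention is
an explicit `FlopConvention` policy object so alternatives can be reported
side by side.

## Objective and metrics

**SI-SNR** projects the estimate onto the reference and scores the residual:
s_target = (⟨ŝ,s⟩/‖s‖²)·s, e_noise = ŝ − s_target,
SI-SNR = 10·log10(‖s_target‖²/‖e_noise‖²). Signals are mean-centered first
(the convention of the metric's origin; the raw projection form used in
some write-ups is available via `zero_mean=False`, and the unit tests of
the hand-worked examples use it). Degenerate ratios are capped at ±300 dB
so losses stay finite.

**SI-SNRi / SDRi** subtract the unprocessed mixture's score from the
estimate's, averaged over sources under the best source-to-estimate
permutation. The improvement baseline is SI-SNR(x, s); the variant that
subtracts SI-SNR(ŝ, x) (the argument order as sometimes printed) is exposed
behind `printed_baseline=True` for comparison but is not the standard
definition.

**SDR** follows the single-source BSS-Eval convention: the estimate is
projected onto the span of the reference and its first 511 delays over the
zero-padded support (length n + 511), making the Gram matrix exactly
Toeplitz; the normal equations are solved by Levinson recursion with a
relative 1e−12 jitter on the zeroth autocorrelation lag to guard
narrow-band references. Note a causally filtered *and truncated* estimate
retains a small tail boundary term under this convention (as in the
reference implementation), so "distortion-free" test cases use references
with silent tails.

**uPIT** training minimizes −max over the C! = 2 permutations of the mean
SI-SNR, per utterance. The differentiable batched loss uses ε = 1e−8
guards in the projection and ratio; validation uses the exact metric.

## Training protocol

* Adam (β1 = 0.9, β2 = 0.999, ε = 1e−8 — conventional defaults; only the
  learning rate is scheduled).
* Learning rate: lr = k1 · d_model^−0.5 · n · warmup_n^−1.5 for steps
  n ≤ warmup_n (k1 = 0.2, warmup_n = 4000, d_model = 256), then
  k2 · 0.98^⌊epoch/2⌋ with k2 = 1.5e−4 — "epoch/2" is integer floor, i.e.
  a 2% decay every two whole epochs. The printed k2 leaves a small
  discontinuity at the warm-up boundary (the ramp ends near 1.98e−4); the
  schedule is implemented exactly as specified.
* Gradient clipping to a global L2 norm of 5 every step.
* Batches are random fixed-length crops (4 s at the full scale) with one
  shared offset for mixture and references, so additivity is preserved.
* Early stopping: "validation does not degenerate" is read as the
  validation SI-SNRi failing to improve for `patience` = 10 consecutive
  epochs; the returned model is the best-validation checkpoint.
* Noise-augmented training injects fresh broadband noise into the *input*
  at a uniform SNR in [0, 25] dB while targets stay clean.

## The synthetic world

Real corpora for this task are built from curated field recordings
(20 species, energy essentially below 8 kHz, resampled to 16 kHz). The
synthetic generator emulates that structure: each "species" owns a disjoint
fundamental-frequency niche partitioning 1–7 kHz (scaled with the rate);
a call is a 1–3-harmonic stack on a linearly swept fundamental with an
exponential attack/decay envelope, peak-normalized, 0.6–2.0 s long; noise
is broadband Gaussian, band-limited Gaussian (insect surrogate), or a
harmonic hum (human-activity surrogate). Everything is a pure function of
its spec and seed.

What the synthetic world does *not* have: reverberation and distance
filtering, amplitude modulation richness and syntax of real song, calls of
the *same* species overlapping, non-stationary noise textures, or
recording-chain artifacts. A green scaled-down training check therefore
establishes that the architecture, loss, and optimization loop learn to
separate spectrally structured sources — not the published full-scale
separation quality (19.3 dB SI-SNRi on ~148 h of real mixtures with GPU
training), which is explicitly not claimed.

### Scaled-down acceptance world

One CPU and minutes (not GPU-days) dictate the acceptance scale: a
4-species corpus, 200 training mixtures without background noise, the tiny
configuration d = 32, B = 2, K = 50, N = 64, 0.5 s crops, batch 4, and
warm-up/peak-rate constants rescaled to the short horizon (warmup 500,
k1 = 1.0, k2 = 1e−3, d_model = 64). 2,000 steps must lift held-out
SI-SNRi from well below zero (an untrained separator emits garbage, so
its "improvement" over the mixture is strongly negative) to ≥5 dB — a
robust floor: the run already reaches ~11 dB by step 600. The noise-robustness check trains the same seed twice (clean vs
noise-augmented, 600 steps each) and asserts only the direction of the
mean SI-SNR gap on 5 dB-SNR validation mixtures.

## Numerical choices

* Encoder/decoder convolutions carry no bias: zero maps to zero and scale
  equivariance is exact. Block convolutions and 1×1 maps carry biases
  (initialized to zero); attention projections do not.
* Layer norm normalizes over the channel axis per position (independent of
  sequence length), with learned per-channel gain/offset and ε = 1e−5.
* Block front conv pads to an output length of ⌈M/TCS⌉ — symmetric
  (TCK−TCS)/2 per side for even M at the default 4/2, extra frame to the
  tail otherwise; the restore deconvolution trims its overshoot
  symmetrically back to M.
* Attention scaling 1/sqrt(d/h), per standard scaled dot-product.
* Inputs shorter than one encoder window are an error; callers pad.
* Dataset invariants are exact by construction: stored sources are
  post-gain, and peak normalization divides mixture and sources jointly,
  so `mixture == sum(sources) (+ noise)` to machine precision and SI-SNR
  (scale-invariant) is unchanged.
* Remainder clips in (8, 24] s keep their natural length (no padding).
* q and noise SNR are drawn uniformly from their ranges ("random" with no
  distribution named).
* The model trains in float32; tests of exact identities run the same
  graph in float64 (the engine follows input dtypes).

## Known limitations

* Fixed C = 2; no source-count estimation, no streaming inference.
* The numpy training loop is single-threaded and orders of magnitude
  slower than a GPU framework; the full-scale 100-epoch protocol is
  supported in code but not desk-feasible.
* The calibrated width d = 72 and the gated output stage are a
  reconstruction constrained by the published parameter/FLOPs figures, not
  a published value; other (d, architecture) pairs inside the reported
  rounding slack exist but fit the FLOPs ladder strictly worse.
* SDR is the single-source BSS-Eval projection; SIR/SAR decompositions and
  perceptual metrics (PESQ/STOI) are out of scope.
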