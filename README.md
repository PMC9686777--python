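# birdsep

Time-domain, single-channel separation of mixed bird vocalizations.

Birds recorded in the field rarely sing alone: overlapping vocalizations
degrade species identification, individual discrimination, and acoustic
diversity indices. `birdsep` implements an efficient end-to-end separation
network for the two-source case — a **dual-path tiny-transformer**
(encoder–separator–decoder) designed to run within the FLOPs and memory
budget of edge and mobile monitoring hardware — together with the full
surrounding pipeline: mixture-dataset construction, uPIT SI-SNR training,
BSS-Eval-style evaluation, an analytic parameter/FLOPs profiler, and a
synthetic bioacoustic corpus generator so everything is testable without
field recordings. The whole stack is numpy/scipy (including backprop); no
deep-learning framework is required.

## The model

A mixture x(t) = s₁(t) + α·s₂(t), with α chosen so the sources sit at a
relative level of q dB, is mapped to estimates ŝᵢ by

1. a learned basis: w = ReLU(Conv1D(x)) (kernel 16, stride 8, N = 256
   filters) — a non-negative STFT surrogate;
2. a dual-path separator at width d = 72: the feature is chunked
   (K = 120, 50% overlap) and processed by B = 6 alternating intra-chunk /
   inter-chunk **tiny-transformer blocks** — a strided depthwise
   convolution (kernel 4, stride 2) replaces positional encodings and
   halves the attention length, multi-head self-attention (h = 4) with a
   layer-normalized residual replaces the feed-forward stack, and a
   transposed convolution restores the length; overlap-add and 1×1
   convolutions emit C = 2 non-negative masks mᵢ;
3. a transposed-convolution decoder: ŝᵢ = ConvTranspose1D(w ⊙ mᵢ).

Training maximizes scale-invariant SNR under utterance-level
permutation-invariant training (uPIT), with a warm-up + 0.98-per-2-epochs
learning-rate schedule, gradient clipping at L2 norm 5, random 4 s crops,
and early stopping. At the default operating point the network carries
**0.4 M trainable parameters** and needs **5.9 GFLOPs** for 4 s of 16 kHz
audio (3.0 G at 8 kHz, 11.7 G at 32 kHz — the cost roughly doubles with the
sampling rate). See `docs/methods.md` for the full model description and
the calibration of the separator width.

## Worked example

Generate a synthetic corpus, mix a dataset, train a small model, and score
it — all from the shell:

```
birdsep synth --n-species 4 --calls 6 --seed 1 --out corpus/
birdsep mix --corpus corpus/ --n 64 --no-noise --seed 1 --out mixtures/
birdsep mix --corpus corpus/ --n 16 --no-noise --seed 2 --out val/
birdsep train --config tiny.yaml --train-manifest mixtures/manifest.jsonl \
              --val-manifest val/manifest.jsonl --out-dir run/ --max-steps 600
birdsep evaluate --model run/checkpoint.npz --manifest val/manifest.jsonl \
                 --report run/report.json
birdsep separate --model run/checkpoint.npz --in mixtures/ex00000_mix.wav --out-dir run/
```

with `tiny.yaml` holding the scaled-down architecture and schedule:

```yaml
model: {sep_dim: 32, n_blocks: 2, chunk_len: 50, n_filters: 64}
train: {crop_len: 0.5, batch_size: 4, warmup_n: 500, k1: 1.0, k2: 0.001,
        d_model: 64, max_epochs: 38, patience: 37}
```

On one CPU this trains in about two minutes and prints (abridged):

```
epoch 0: loss=26.255 val SI-SNRi=-20.73 dB
epoch 5: loss=6.614 val SI-SNRi=-0.60 dB
epoch 36: loss=-7.958 val SI-SNRi=10.78 dB
stopped after epoch 38; best validation SI-SNRi 10.78 dB (epoch 36); checkpoint: run/checkpoint.npz
mean SI-SNRi 10.78 dB, mean SDRi 13.43 dB over 16 examples
```

The loss is the negative best-permutation mean SI-SNR of the training
crops (in dB; more negative is better), and SI-SNRi/SDRi measure how many
dB the estimates improve on the raw mixture against the clean references —
here ≈11–13 dB on held-out mixtures after 600 optimization steps on a
4-species synthetic corpus. An untrained model scores far below 0 dB.

The profiler reproduces the efficiency figures of the full-size network in
seconds:

```
$ birdsep profile --rate 16000 --duration 4
params: 355,248 (0.4 M); FLOPs @ 16000 Hz x 4.0 s: 5.907 G
```

## Library surface

Every CLI command is a thin wrapper over importable functions:
`birdsep.synth.generate_corpus`, `birdsep.dataset.build_dataset`,
`birdsep.model.SeparationModel`, `birdsep.train.train`,
`birdsep.metrics.{si_snr, si_snr_improvement, sdr, upit_loss}`,
`birdsep.profiler.{count_params, count_flops}`; see the module docstrings.

## Acceptance script

`scripts/acceptance.py` recomputes the headline efficiency numbers from
scratch — it builds the default network, counts its trainable parameters,
and runs the analytic FLOPs counter for 4-second inputs at 8, 16, and
32 kHz:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

writing one JSON object with entries `t1` (parameters, M) and `t2`–`t4`
(GFLOPs at 16/8/32 kHz).
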