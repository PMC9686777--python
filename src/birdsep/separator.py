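"""Dual-path tiny-transformer separator.

The separator estimates C non-negative masks over the encoder's latent
feature.  Long feature sequences are handled with dual-path processing:

1. segmentation — slice the (d, L) feature into S chunks of length K with
   50% overlap (hop P = K/2), zero-padding so every original frame is
   covered by exactly two chunks, giving a tensor D of shape (d, K, S);
2. B repetitions of an intra-chunk pass (sequence length K, applied to each
   chunk) followed by an inter-chunk pass (sequence length S, applied to
   each within-chunk position) of the tiny-transformer block;
3. a 1x1 output projection to C*d channels;
4. per source: overlap-add back to (d, L), a gated output stage
   (tanh conv ⊙ sigmoid conv, as in the dual-path RNN lineage), then a 1x1
   convolution to the encoder width N and ReLU, yielding the masks.

The tiny-transformer block replaces positional encodings and the
feed-forward network of a standard transformer encoder with a strided
convolution in front (halving the sequence for stride 2, so attention costs
a quarter) and a transposed convolution behind that restores the length:

    Z   = conv1d(X)                          # stride TCS, kernel TCK
    Mid = LN(Z + MultiHeadAttention(Z))
    Y   = conv1d_transpose(ReLU(Mid))        # back to the input length
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, no_grad
from .config import ModelConfig
from .nn import (
    ChannelLayerNorm,
    Conv1d,
    ConvTranspose1d,
    DepthwiseConv1d,
    DepthwiseConvTranspose1d,
    Module,
)

__all__ = [
    "ChunkTensor",
    "segment_plan",
    "segment",
    "overlap_add",
    "TinyTransformerBlock",
    "tiny_transformer_forward",
    "intra_pass",
    "inter_pass",
    "dual_path",
    "DualPathSeparator",
]


# --------------------------------------------------------------------------
# Segmentation / overlap-add
# --------------------------------------------------------------------------

def segment_plan(L: int, K: int) -> tuple[int, int, int, int]:
    """Padding bookkeeping for chunking L frames into length-K chunks.

    Returns (P, pad_front, pad_tail, S): hop P = K/2, a front pad of P, a
    tail pad of pad_tail + P, and the chunk count S = total/P - 1.  The
    front/tail pads of P frames give the first and last original frame their
    second covering chunk; pad_tail < P aligns the total to a multiple of P.
    """
    if K % 2 != 0:
        raise ValueError(f"chunk length K must be even, got {K}")
    if L < 1:
        raise ValueError("cannot segment an empty feature")
    P = K // 2
    pad_front = P
    pad_tail = (-(pad_front + L)) % P
    total = pad_front + L + pad_tail + P
    S = total // P - 1
    return P, pad_front, pad_tail, S


@dataclass
class ChunkTensor:
    """Segmented feature (d, K, S) plus the bookkeeping to invert exactly."""

    values: np.ndarray  # (d, K, S)
    pad_front: int
    pad_tail: int
    original_len: int

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("ChunkTensor values must be (d, K, S)")
        K = self.values.shape[1]
        P, pf, pt, S = segment_plan(self.original_len, K)
        if (pf, pt, S) != (self.pad_front, self.pad_tail, self.values.shape[2]):
            raise ValueError("inconsistent ChunkTensor bookkeeping")


def segment(f: np.ndarray, K: int) -> ChunkTensor:
    """Slice a (d, L) feature into 50%-overlapping chunks of length K."""
    f = np.asarray(f)
    if f.ndim != 2:
        raise ValueError("segment expects a 2-axis (d, L) feature")
    d, L = f.shape
    P, pad_front, pad_tail, S = segment_plan(L, K)
    padded = np.pad(f, ((0, 0), (pad_front, pad_tail + P)))
    blocks = padded.reshape(d, S + 1, P)
    chunks = np.concatenate([blocks[:, :-1, :], blocks[:, 1:, :]], axis=2)  # (d,S,K)
    return ChunkTensor(
        np.ascontiguousarray(chunks.transpose(0, 2, 1)), pad_front, pad_tail, L
    )


def overlap_add(D: ChunkTensor) -> np.ndarray:
    """Invert :func:`segment` exactly: sum at hop P, halve, strip the pads."""
    d, K, S = D.values.shape
    P = K // 2
    L = D.original_len
    total = (S + 1) * P
    acc = np.zeros((d, total), dtype=D.values.dtype)
    chunks = D.values.transpose(0, 2, 1)  # (d, S, K)
    acc.reshape(d, S + 1, P)[:, :-1, :] += chunks[:, :, :P]
    acc.reshape(d, S + 1, P)[:, 1:, :] += chunks[:, :, P:]
    return acc[:, D.pad_front : D.pad_front + L] / 2.0


def _segment_t(x: Tensor, K: int) -> tuple[Tensor, tuple[int, int, int, int]]:
    """Batched autodiff segmentation: (B, d, L) -> (B, d, K, S)."""
    B, d, L = x.shape
    plan = segment_plan(L, K)
    P, pad_front, pad_tail, S = plan
    padded = x.pad1d(pad_front, pad_tail + P)              # (B, d, (S+1)P)
    blocks = padded.reshape(B, d, S + 1, P)
    first = blocks[:, :, :-1, :].pad1d(0, P)               # left half of chunks
    second = blocks[:, :, 1:, :].pad1d(P, 0)               # right half of chunks
    chunks = first + second                                # (B, d, S, K)
    return chunks.transpose(0, 1, 3, 2), plan


def _overlap_add_t(D: Tensor, plan: tuple[int, int, int, int], L: int) -> Tensor:
    """Batched autodiff overlap-add: (B, d, K, S) -> (B, d, L)."""
    P, pad_front, _pad_tail, S = plan
    B, d, K, _S = D.shape
    chunks = D.transpose(0, 1, 3, 2)                       # (B, d, S, K)
    left = chunks[:, :, :, :P].reshape(B, d, S * P).pad1d(0, P)
    right = chunks[:, :, :, P:].reshape(B, d, S * P).pad1d(P, 0)
    acc = left + right                                     # (B, d, (S+1)P)
    return acc[:, :, pad_front : pad_front + L] * 0.5


# --------------------------------------------------------------------------
# Tiny-transformer block
# --------------------------------------------------------------------------

def _front_padding(M: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Pad so the strided conv outputs ceil(M/stride) frames.

    For kernel 4 / stride 2 and even M this is the symmetric 1-frame pad per
    side; for general shapes the extra frame goes to the tail.
    """
    out = math.ceil(M / stride)
    pad_total = stride * (out - 1) + kernel - M
    front = pad_total // 2
    return front, pad_total - front, out


class TinyTransformerBlock(Module):
    """Strided conv -> multi-head self-attention -> LN residual -> ReLU -> deconv."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator,
                 dtype=np.float32):
        d, h = cfg.sep_dim, cfg.n_heads
        self.d, self.h = d, h
        self.kernel, self.stride = cfg.tt_kernel, cfg.tt_stride
        if cfg.tt_depthwise:
            self.front = DepthwiseConv1d(
                d, cfg.tt_kernel, cfg.tt_stride, rng=rng, dtype=dtype
            )
            self.restore = DepthwiseConvTranspose1d(
                d, cfg.tt_kernel, cfg.tt_stride, rng=rng, dtype=dtype
            )
        else:
            self.front = Conv1d(
                d, d, cfg.tt_kernel, cfg.tt_stride, rng=rng, dtype=dtype
            )
            self.restore = ConvTranspose1d(
                d, d, cfg.tt_kernel, cfg.tt_stride, rng=rng, dtype=dtype
            )
        scale = 1.0 / math.sqrt(d)
        self.w_q = Parameter((rng.standard_normal((d, d)) * scale).astype(dtype))
        self.w_k = Parameter((rng.standard_normal((d, d)) * scale).astype(dtype))
        self.w_v = Parameter((rng.standard_normal((d, d)) * scale).astype(dtype))
        self.w_o = Parameter((rng.standard_normal((d, d)) * scale).astype(dtype))
        self.norm = ChannelLayerNorm(d, dtype=dtype)

    def _attention(self, z: Tensor, return_weights: bool = False):
        """Multi-head scaled dot-product self-attention on (B, d, M')."""
        B, d, M = z.shape
        h, dh = self.h, d // self.h
        zt = z.transpose(0, 2, 1)                          # (B, M', d)
        heads = []
        for w in (self.w_q, self.w_k, self.w_v):
            proj = zt @ w                                  # (B, M', d)
            heads.append(proj.reshape(B, M, h, dh).transpose(0, 2, 1, 3))
        q, k, v = heads                                    # each (B, h, M', dh)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = logits.softmax(axis=-1)                     # (B, h, M', M')
        ctx = attn @ v                                     # (B, h, M', dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, M, d)
        out = (ctx @ self.w_o).transpose(0, 2, 1)          # (B, d, M')
        if return_weights:
            return out, attn
        return out

    def __call__(self, x: Tensor) -> Tensor:
        B, d, M = x.shape
        if M < self.kernel:
            raise ValueError(
                f"sequence length {M} shorter than block kernel {self.kernel}"
            )
        front, tail, _out = _front_padding(M, self.kernel, self.stride)
        z = self.front(x.pad1d(front, tail))               # (B, d, ceil(M/TCS))
        mid = self.norm(z + self._attention(z))
        y = self.restore(mid.relu())                       # may overshoot M
        raw = y.shape[-1]
        trim = (raw - M) // 2
        return y[:, :, trim : trim + M]

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        """Attention weights (h, M', M') for a single (d, M) sequence."""
        front, tail, _ = _front_padding(X.shape[-1], self.kernel, self.stride)
        with no_grad():
            z = self.front(Tensor(np.asarray(X)[None]).pad1d(front, tail))
            _, attn = self._attention(z, return_weights=True)
        return attn.data[0]


def tiny_transformer_forward(X: np.ndarray, block: TinyTransformerBlock) -> np.ndarray:
    """Apply one block to a single (d, M) sequence; output shape equals input."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("tiny_transformer_forward expects a (d, M) sequence")
    with no_grad():
        out = block(Tensor(X[None]))
    return out.data[0]


# --------------------------------------------------------------------------
# Dual-path passes (single-example API; the model uses the batched Tensors)
# --------------------------------------------------------------------------

def _replace(D: ChunkTensor, values: np.ndarray) -> ChunkTensor:
    return ChunkTensor(values, D.pad_front, D.pad_tail, D.original_len)


def intra_pass(D: ChunkTensor, block: TinyTransformerBlock) -> ChunkTensor:
    """Apply the block to each chunk independently (sequence length K)."""
    d, K, S = D.values.shape
    batched = np.ascontiguousarray(D.values.transpose(2, 0, 1))  # (S, d, K)
    with no_grad():
        out = block(Tensor(batched))
    return _replace(D, np.ascontiguousarray(out.data.transpose(1, 2, 0)))


def inter_pass(D: ChunkTensor, block: TinyTransformerBlock) -> ChunkTensor:
    """Apply the block across chunks at each within-chunk position (length S)."""
    d, K, S = D.values.shape
    batched = np.ascontiguousarray(D.values.transpose(1, 0, 2))  # (K, d, S)
    with no_grad():
        out = block(Tensor(batched))
    return _replace(D, np.ascontiguousarray(out.data.transpose(1, 0, 2)))


def dual_path(D: ChunkTensor, blocks: list[TinyTransformerBlock]) -> ChunkTensor:
    """B alternating intra/inter passes; `blocks` holds them interleaved."""
    if len(blocks) % 2 != 0:
        raise ValueError("dual_path needs an even number of blocks (intra+inter)")
    for b in range(len(blocks) // 2):
        D = intra_pass(D, blocks[2 * b])
        D = inter_pass(D, blocks[2 * b + 1])
    return D


# --------------------------------------------------------------------------
# Full separator
# --------------------------------------------------------------------------

class DualPathSeparator(Module):
    """Latent feature (B, N, L) -> C masks (B, C, N, L)."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.cfg = cfg
        N, d = cfg.n_filters, cfg.sep_dim
        self.in_norm = ChannelLayerNorm(N, dtype=dtype)
        self.bottleneck = Conv1d(N, d, 1, bias=False, rng=rng, dtype=dtype)
        self.blocks = [
            TinyTransformerBlock(cfg, rng=rng, dtype=dtype)
            for _ in range(2 * cfg.n_blocks)
        ]
        self.out_proj = Conv1d(d, cfg.n_sources * d, 1, rng=rng, dtype=dtype)
        self.gate_tanh = [
            Conv1d(d, d, 1, rng=rng, dtype=dtype) for _ in range(cfg.n_sources)
        ]
        self.gate_sigmoid = [
            Conv1d(d, d, 1, rng=rng, dtype=dtype) for _ in range(cfg.n_sources)
        ]
        self.mask_convs = [
            Conv1d(d, N, 1, rng=rng, dtype=dtype) for _ in range(cfg.n_sources)
        ]

    def __call__(self, w: Tensor) -> list[Tensor]:
        cfg = self.cfg
        B, N, L = w.shape
        d, C, K = cfg.sep_dim, cfg.n_sources, cfg.chunk_len
        f = self.bottleneck(self.in_norm(w))               # (B, d, L)
        D, plan = _segment_t(f, K)                         # (B, d, K, S)
        S = D.shape[-1]
        for b in range(cfg.n_blocks):
            intra, inter = self.blocks[2 * b], self.blocks[2 * b + 1]
            # intra: each chunk is a sequence of length K
            x = D.transpose(0, 3, 1, 2).reshape(B * S, d, K)
            x = intra(x)
            D = x.reshape(B, S, d, K).transpose(0, 2, 3, 1)
            # inter: each within-chunk position is a sequence of length S
            x = D.transpose(0, 2, 1, 3).reshape(B * K, d, S)
            x = inter(x)
            D = x.reshape(B, K, d, S).transpose(0, 2, 1, 3)
        flat = D.reshape(B, d, K * S)
        flat = self.out_proj(flat)                         # (B, C*d, K*S)
        Dout = flat.reshape(B, C * d, K, S)
        masks = []
        for i in range(C):
            slab = Dout[:, i * d : (i + 1) * d, :, :]
            merged = _overlap_add_t(slab, plan, L)         # (B, d, L)
            gated = self.gate_tanh[i](merged).tanh() * \
                self.gate_sigmoid[i](merged).sigmoid()
            masks.append(self.mask_convs[i](gated).relu())  # (B, N, L)
        return masks
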