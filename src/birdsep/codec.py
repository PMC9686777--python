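"""Learned waveform front-end and back-end.

The encoder is a single bias-free 1-D convolution followed by ReLU: it plays
the role of an STFT with a learned basis, mapping a waveform of length T to a
non-negative latent feature w of shape (N, L) with
L = floor((T - kernel)/stride) + 1.  The decoder is the matching bias-free
transposed convolution that reconstructs a waveform from a masked feature.
Bias-free maps make zero-in/zero-out and scale equivariance exact.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, no_grad
from .config import ModelConfig
from .nn import Conv1d, ConvTranspose1d, Module

__all__ = ["Encoder", "Decoder", "latent_frames", "apply_mask"]


def latent_frames(n_samples: int, cfg: ModelConfig) -> int:
    """Number of latent frames L produced by the encoder for a T-sample input."""
    if n_samples < cfg.enc_kernel:
        raise ValueError(
            f"input length {n_samples} shorter than encoder kernel {cfg.enc_kernel}"
        )
    return (n_samples - cfg.enc_kernel) // cfg.enc_stride + 1


class Encoder(Module):
    """w = ReLU(Conv1D(x)); bias-free, so w >= 0 and encode(0) = 0."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.cfg = cfg
        self.conv = Conv1d(
            1, cfg.n_filters, cfg.enc_kernel, cfg.enc_stride,
            bias=False, rng=rng, dtype=dtype,
        )

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x).relu()

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Encode a mono waveform (T,) to a latent feature (N, L)."""
        x = np.asarray(x)
        if x.ndim != 1:
            raise ValueError("encode expects a mono waveform (T,)")
        latent_frames(x.shape[0], self.cfg)  # validates length
        with no_grad():
            w = self(Tensor(x[None, None, :].astype(self.conv.weight.data.dtype)))
        return w.data[0]


class Decoder(Module):
    """ŝ = ConvTranspose1D(w ⊙ m); same kernel and stride as the encoder."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.cfg = cfg
        self.deconv = ConvTranspose1d(
            cfg.n_filters, 1, cfg.enc_kernel, cfg.enc_stride,
            bias=False, rng=rng, dtype=dtype,
        )

    def __call__(self, z: Tensor, length: int) -> Tensor:
        """Decode (B, N, L) to (B, 1, length), trimming or zero-padding the tail."""
        y = self.deconv(z)
        raw = y.shape[-1]
        if raw >= length:
            return y[:, :, :length]
        return y.pad1d(0, length - raw)

    def decode(self, z: np.ndarray, length: int) -> np.ndarray:
        """Decode a latent feature (N, L) to a waveform (length,)."""
        z = np.asarray(z)
        if z.ndim != 2 or z.shape[0] != self.cfg.n_filters:
            raise ValueError(
                f"decode expects an (N, L) feature with N={self.cfg.n_filters}"
            )
        with no_grad():
            y = self(Tensor(z[None].astype(self.deconv.weight.data.dtype)), length)
        return y.data[0, 0]


def apply_mask(w: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Elementwise product of a latent feature and one mask (both (N, L))."""
    w = np.asarray(w)
    m = np.asarray(m)
    if w.shape != m.shape:
        raise ValueError(f"feature/mask shape mismatch: {w.shape} vs {m.shape}")
    return w * m
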