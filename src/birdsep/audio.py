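"""Mono 16-bit PCM WAV I/O and the ``Waveform`` container.

Samples are held as float64 in nominal range [-1, 1]; 16-bit integers are
scaled by 1/32768 on read and clipped on write.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["Waveform", "read_wav", "write_wav"]

_PCM_SCALE = 32768.0


@dataclass(frozen=True)
class Waveform:
    """A mono sample sequence with its sampling rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform expects a mono (1-D) sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return len(self) / self.rate

    def energy(self) -> float:
        return float(np.sum(self.samples**2))

    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self) else 0.0


def read_wav(path: str | Path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM_SCALE
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Waveform(samples, int(rate))


def write_wav(path: str | Path, w: Waveform) -> None:
    clipped = np.clip(w.samples, -1.0, 32767.0 / _PCM_SCALE)
    wavfile.write(path, w.rate, np.round(clipped * _PCM_SCALE).astype(np.int16))
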