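"""End-to-end separation model: encoder -> dual-path separator -> decoder."""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor, no_grad
from .codec import Decoder, Encoder, latent_frames
from .config import ModelConfig, RunConfig
from .nn import Module
from .separator import DualPathSeparator

__all__ = ["SeparationModel", "build_model", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT = 1


class SeparationModel(Module):
    """Time-domain single-channel separator for C sources."""

    def __init__(self, cfg: ModelConfig, *, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng=rng, dtype=dtype)
        self.separator = DualPathSeparator(cfg, rng=rng, dtype=dtype)
        self.decoder = Decoder(cfg, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Separate a batch (B, 1, T) into C estimates, each (B, 1, T)."""
        T = x.shape[-1]
        latent_frames(T, self.cfg)  # validates length
        w = self.encoder(x)
        masks = self.separator(w)
        return [self.decoder(w * m, T) for m in masks]

    __call__ = forward

    def separate(self, x: np.ndarray) -> list[np.ndarray]:
        """Separate a mono waveform (T,) into C waveforms of the same length."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError("separate expects a mono waveform (T,)")
        dtype = self.encoder.conv.weight.data.dtype
        with no_grad():
            outs = self.forward(Tensor(x[None, None, :].astype(dtype)))
        return [o.data[0, 0].copy() for o in outs]


def build_model(cfg: ModelConfig | None = None, *, seed: int = 0,
                dtype=np.float32) -> SeparationModel:
    return SeparationModel(cfg or ModelConfig(), seed=seed, dtype=dtype)


def save_checkpoint(path: str | Path, model: SeparationModel,
                    run_cfg: RunConfig | None = None, extra: dict | None = None):
    """Single-archive checkpoint: weights + config snapshot + format version."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "run_config": (run_cfg.to_dict() if run_cfg is not None
                       else RunConfig(model=model.cfg).to_dict()),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[SeparationModel, RunConfig, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format')}")
        run_cfg = RunConfig.from_dict(meta["run_config"])
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = SeparationModel(run_cfg.model)
    model.load_state_dict(state)
    return model, run_cfg, meta.get("extra", {})
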