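"""Configuration schema for the separation network and its training loop.

``ModelConfig`` holds the architecture hyperparameters.  Defaults are the
published operating point of the network: encoder kernel 16 with stride 8,
256 encoder filters, chunk length K=120, B=6 dual-path repetitions, 4
attention heads, and a kernel-4/stride-2 strided convolution inside each
tiny-transformer block.  The separator width ``sep_dim`` is not published;
its default (see ``birdsep.profiler``) was calibrated so that the parameter
count and analytic FLOPs reproduce the printed efficiency figures.

Configs round-trip losslessly through dicts and YAML; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "TrainConfig", "RunConfig", "load_config", "save_config"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the dual-path tiny-transformer separator."""

    enc_kernel: int = 16      # encoder conv kernel, samples
    enc_stride: int = 8       # encoder conv stride; half the kernel by convention
    n_filters: int = 256      # encoder/decoder basis size N
    sep_dim: int = 72         # separator channel width d (calibrated; see profiler)
    chunk_len: int = 120      # segmentation chunk length K
    n_blocks: int = 6         # dual-path repetitions B (each = intra + inter)
    n_heads: int = 4          # attention heads h
    tt_kernel: int = 4        # strided conv kernel inside the block (TCK)
    tt_stride: int = 2        # strided conv stride inside the block (TCS)
    tt_depthwise: bool = True # depthwise front/restore convs (calibrated)
    n_sources: int = 2        # number of sources C

    def __post_init__(self):
        if self.chunk_len % 2 != 0:
            raise ValueError(f"chunk_len (K) must be even, got {self.chunk_len}")
        if self.sep_dim % self.n_heads != 0:
            raise ValueError(
                f"sep_dim ({self.sep_dim}) must be divisible by "
                f"n_heads ({self.n_heads})"
            )
        if self.tt_stride < 1:
            raise ValueError(f"tt_stride must be >= 1, got {self.tt_stride}")
        if self.tt_kernel < self.tt_stride:
            raise ValueError("tt_kernel must be >= tt_stride")
        if self.enc_kernel < 1 or self.enc_stride < 1:
            raise ValueError("enc_kernel and enc_stride must be positive")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        for name in ("n_filters", "n_blocks", "n_heads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class TrainConfig:
    """Training protocol: uPIT SI-SNR objective with warm-up + decay schedule."""

    k1: float = 0.2           # warm-up scale of the lr schedule
    k2: float = 1.5e-4        # post-warm-up base learning rate
    warmup_n: int = 4000      # warm-up steps
    d_model: int = 256        # width constant in the warm-up formula
    decay: float = 0.98       # lr decay factor applied every two epochs
    clip_norm: float = 5.0    # global gradient L2-norm ceiling
    crop_len: float = 4.0     # random crop length, seconds
    batch_size: int = 2
    max_epochs: int = 100
    patience: int = 10        # early-stop epochs without validation improvement
    seed: int = 0
    noise_augment: bool = False
    noise_snr_range: tuple[float, float] = (0.0, 25.0)

    def __post_init__(self):
        if self.warmup_n <= 0:
            raise ValueError("warmup_n must be positive")
        if not (0 < self.patience < self.max_epochs):
            raise ValueError("need 0 < patience < max_epochs")
        if self.crop_len <= 0:
            raise ValueError("crop_len must be positive")
        self.noise_snr_range = tuple(float(v) for v in self.noise_snr_range)
        if len(self.noise_snr_range) != 2:
            raise ValueError("noise_snr_range must be (lo, hi)")


@dataclass
class RunConfig:
    """Everything a command needs: model + training + paths + global seed."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    rate: int = 16000
    out_dir: str = "runs"
    log_level: str = "info"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        model = _build(ModelConfig, d.pop("model", {}))
        train = _build(TrainConfig, d.pop("train", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"model", "train"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(model=model, train=train, **d)


def _build(cls, d: dict):
    if not isinstance(d, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(d)}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    typed = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.type in ("int", int) and isinstance(v, float) and v != int(v):
            raise ValueError(f"{cls.__name__}.{f.name} must be an integer, got {v}")
        typed[f.name] = v
    return cls(**typed)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
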