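"""Mixture construction: clipping, resampling, relative-level mixing,
SNR-controlled noise injection, normalization, and dataset manifests.

The supervised training unit is a :class:`MixtureExample`: a mixture
waveform together with its (post-gain, post-normalization) source
references, so that ``mixture == sum(sources) (+ noise)`` holds to machine
precision and the stored sources are exactly the additive components a
separator should recover.

Two sources are mixed at a relative level of q dB,

    s(t) = s1(t) + alpha * s2(t),
    alpha = sqrt( sum(s1^2) / (10^(q/10) * sum(s2^2)) ),

so the energy ratio of s1 to alpha*s2 is exactly q dB.  Background noise is
optionally added at a random SNR (default 0–25 dB, measured against the
mixture), and the result is jointly peak-normalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .audio import Waveform, read_wav, write_wav
from .synth import SyntheticCorpus

__all__ = [
    "MixtureExample",
    "DatasetManifest",
    "clip_recording",
    "resample",
    "compute_gain",
    "mix_pair",
    "add_noise_at_snr",
    "normalize_example",
    "make_example",
    "build_dataset",
    "load_examples",
]


@dataclass
class MixtureExample:
    """Mixture + aligned source references + mixing metadata."""

    mixture: Waveform
    sources: list[Waveform]
    q: float                      # relative level of the two sources, dB
    alpha: float                  # gain applied to the second source
    noise_snr: float | None = None
    noise: Waveform | None = None # scaled noise actually added, if any
    normalization_factor: float = 1.0
    species: tuple[str, ...] = ()

    def __post_init__(self):
        n, rate = len(self.mixture), self.mixture.rate
        parts = list(self.sources) + ([self.noise] if self.noise else [])
        for w in parts:
            if len(w) != n or w.rate != rate:
                raise ValueError("all waveforms must share length and rate")

    def residual(self) -> float:
        """max |mixture - (sum of sources + noise)|; 0 by construction."""
        acc = np.zeros(len(self.mixture))
        for s in self.sources:
            acc += s.samples
        if self.noise is not None:
            acc += self.noise.samples
        return float(np.max(np.abs(self.mixture.samples - acc)))


@dataclass
class DatasetManifest:
    records: list[dict]
    rate: int
    seed: int
    root: str = "."


def clip_recording(w: Waveform, max_len: float = 24.0,
                   min_keep: float = 8.0) -> list[Waveform]:
    """Cut into `max_len`-second clips; keep a remainder only if > `min_keep` s.

    Inputs not exceeding `max_len` are returned unchanged.
    """
    if not (max_len > min_keep > 0):
        raise ValueError("need max_len > min_keep > 0")
    if len(w) == 0:
        raise ValueError("cannot clip an empty waveform")
    seg = int(round(max_len * w.rate))
    if len(w) <= seg:
        return [w]
    clips = []
    pos = 0
    while len(w) - pos > seg:
        clips.append(Waveform(w.samples[pos : pos + seg], w.rate))
        pos += seg
    remainder = len(w) - pos
    if remainder > min_keep * w.rate:
        clips.append(Waveform(w.samples[pos:], w.rate))
    return clips


def resample(w: Waveform, target_rate: int = 16000) -> Waveform:
    """Band-limited (polyphase) resampling."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == w.rate:
        return w
    frac = Fraction(target_rate, w.rate)
    out = sps.resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(out, target_rate)


def compute_gain(s1: Waveform, s2: Waveform, q: float) -> float:
    """Gain alpha that sets the s1 : alpha*s2 energy ratio to q dB."""
    e2 = s2.energy()
    if e2 == 0:
        raise ValueError("second source has zero energy; cannot set a level")
    return float(np.sqrt(s1.energy() / (10.0 ** (q / 10.0) * e2)))


def mix_pair(s1: Waveform, s2: Waveform, q: float,
             species: tuple[str, ...] = ()) -> MixtureExample:
    """Mix two equal-length sources at relative level q dB (no normalization)."""
    if len(s1) != len(s2) or s1.rate != s2.rate:
        raise ValueError("sources must share length and rate")
    alpha = compute_gain(s1, s2, q)
    scaled = Waveform(alpha * s2.samples, s2.rate)
    mixture = Waveform(s1.samples + scaled.samples, s1.rate)
    return MixtureExample(mixture, [s1, scaled], q=q, alpha=alpha,
                          species=species)


def add_noise_at_snr(x: Waveform, noise: Waveform, snr: float) -> Waveform:
    """x + g*noise with the x : g*noise energy ratio equal to `snr` dB."""
    if len(x) != len(noise) or x.rate != noise.rate:
        raise ValueError("signal and noise must share length and rate")
    en = noise.energy()
    if en == 0:
        raise ValueError("noise has zero energy")
    g = float(np.sqrt(x.energy() / (10.0 ** (snr / 10.0) * en)))
    return Waveform(x.samples + g * noise.samples, x.rate)


def _noise_gain(x: Waveform, noise: Waveform, snr: float) -> float:
    en = noise.energy()
    if en == 0:
        raise ValueError("noise has zero energy")
    return float(np.sqrt(x.energy() / (10.0 ** (snr / 10.0) * en)))


def normalize_example(e: MixtureExample) -> MixtureExample:
    """Joint peak normalization: divide mixture, sources, and noise by the
    mixture's peak so relative levels (and SI-SNR) are unchanged."""
    peak = e.mixture.peak()
    if peak == 0:
        raise ValueError("cannot normalize an all-zero mixture")
    factor = 1.0 / peak
    scale = lambda w: Waveform(w.samples * factor, w.rate)
    return replace(
        e,
        mixture=scale(e.mixture),
        sources=[scale(s) for s in e.sources],
        noise=scale(e.noise) if e.noise is not None else None,
        normalization_factor=e.normalization_factor * factor,
    )


def make_example(
    corpus: SyntheticCorpus,
    rng: np.random.Generator,
    q_range: tuple[float, float] = (-5.0, 5.0),
    noise_snr_range: tuple[float, float] | None = (0.0, 25.0),
    noise_bank: list[Waveform] | None = None,
) -> MixtureExample:
    """One normalized training example from two different random species.

    The two calls are placed at random offsets inside a clip as long as the
    longer call, then mixed at q ~ U(q_range); optional noise (drawn from
    `noise_bank`, or broadband Gaussian) is added at SNR ~ U(noise_snr_range).
    """
    labels = corpus.species
    i, j = rng.choice(len(labels), size=2, replace=False)
    c1 = corpus.calls[labels[i]][rng.integers(len(corpus.calls[labels[i]]))]
    c2 = corpus.calls[labels[j]][rng.integers(len(corpus.calls[labels[j]]))]
    n = max(len(c1), len(c2))

    def place(c: Waveform) -> Waveform:
        out = np.zeros(n)
        off = int(rng.integers(0, n - len(c) + 1))
        out[off : off + len(c)] = c.samples
        return Waveform(out, corpus.rate)

    q = float(rng.uniform(*q_range))
    e = mix_pair(place(c1), place(c2), q, species=(labels[i], labels[j]))
    if noise_snr_range is not None:
        snr = float(rng.uniform(*noise_snr_range))
        if noise_bank:
            src = noise_bank[rng.integers(len(noise_bank))]
            reps = int(np.ceil(n / len(src)))
            noise = Waveform(np.tile(src.samples, reps)[:n], corpus.rate)
        else:
            noise = Waveform(rng.standard_normal(n), corpus.rate)
        g = _noise_gain(e.mixture, noise, snr)
        scaled = Waveform(g * noise.samples, corpus.rate)
        e = replace(
            e,
            mixture=Waveform(e.mixture.samples + scaled.samples, corpus.rate),
            noise=scaled,
            noise_snr=snr,
        )
    return normalize_example(e)


def build_dataset(
    corpus: SyntheticCorpus,
    n_examples: int,
    q_range: tuple[float, float] = (-5.0, 5.0),
    noise_snr_range: tuple[float, float] | None = (0.0, 25.0),
    seed: int = 0,
    out_dir: str | Path | None = None,
    noise_bank: list[Waveform] | None = None,
) -> tuple[DatasetManifest, list[MixtureExample]]:
    """Generate `n_examples` mixtures; write WAVs + JSONL manifest if out_dir.

    Returns the manifest and the in-memory examples (in manifest order);
    fully reproducible from `seed`.
    """
    if n_examples <= 0:
        raise ValueError("n_examples must be positive")
    rng = np.random.default_rng(seed)
    records, examples = [], []
    root = Path(out_dir) if out_dir is not None else None
    if root is not None:
        root.mkdir(parents=True, exist_ok=True)
    for idx in range(n_examples):
        e = make_example(corpus, rng, q_range, noise_snr_range, noise_bank)
        rec = {
            "q": e.q,
            "alpha": e.alpha,
            "noise_snr": e.noise_snr,
            "species": list(e.species),
            "seed": seed,
        }
        if root is not None:
            mix_path = f"ex{idx:05d}_mix.wav"
            src_paths = [f"ex{idx:05d}_src{k+1}.wav" for k in range(len(e.sources))]
            write_wav(root / mix_path, e.mixture)
            for p, s in zip(src_paths, e.sources):
                write_wav(root / p, s)
            rec |= {"mixture_path": mix_path, "source_paths": src_paths}
        records.append(rec)
        examples.append(e)
    manifest = DatasetManifest(records, corpus.rate, seed,
                               str(root) if root is not None else ".")
    if root is not None:
        with open(root / "manifest.jsonl", "w") as fh:
            fh.write(json.dumps({"rate": corpus.rate, "seed": seed}) + "\n")
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
    return manifest, examples


def load_examples(manifest_path: str | Path) -> list[MixtureExample]:
    """Load a written dataset back into memory (references stay exact up to
    16-bit quantization of the WAV files)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    examples = []
    with open(manifest_path) as fh:
        header = json.loads(fh.readline())
        for line in fh:
            rec = json.loads(line)
            mixture = read_wav(root / rec["mixture_path"])
            sources = [read_wav(root / p) for p in rec["source_paths"]]
            resid = mixture.samples - sum(s.samples for s in sources)
            noise = None
            if rec.get("noise_snr") is not None:
                noise = Waveform(resid, mixture.rate)
            examples.append(
                MixtureExample(
                    mixture, sources, q=rec["q"],
                    alpha=rec.get("alpha", 1.0),
                    noise_snr=rec.get("noise_snr"), noise=noise,
                    species=tuple(rec.get("species", ())),
                )
            )
    _ = header
    return examples
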