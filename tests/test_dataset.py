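"""Mixture construction: clipping rule, gains, noise injection, normalization."""

import numpy as np
import pytest

from birdsep.audio import Waveform
from birdsep.dataset import (
    add_noise_at_snr,
    build_dataset,
    clip_recording,
    compute_gain,
    load_examples,
    mix_pair,
    normalize_example,
    resample,
)
from birdsep.metrics import si_snr


def _wave(samples, rate=16000):
    return Waveform(np.asarray(samples, dtype=float), rate)


def _tone(freq, duration, rate):
    t = np.arange(int(duration * rate)) / rate
    return Waveform(np.sin(2 * np.pi * freq * t), rate)


class TestClipRecording:
    @pytest.mark.parametrize(
        "dur,expected",
        [(60.0, [24.0, 24.0, 12.0]),   # remainder 12 s > 8 s -> kept
         (50.0, [24.0, 24.0]),         # remainder 2 s <= 8 s -> discarded
         (20.0, [20.0])],              # below threshold -> unchanged
    )
    def test_clipping_rule(self, dur, expected):
        rate = 1000
        w = _wave(np.arange(int(dur * rate)), rate)
        clips = clip_recording(w)
        assert [c.duration for c in clips] == expected

    def test_conservation_and_bound(self, rng):
        rate = 500
        w = _wave(rng.standard_normal(int(93.7 * rate)), rate)
        clips = clip_recording(w)
        assert sum(len(c) for c in clips) <= len(w)
        assert all(c.duration <= 24.0 for c in clips)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clip_recording(_wave([]))


class TestResample:
    def test_same_rate_identity(self, rng):
        w = _wave(rng.standard_normal(100))
        assert resample(w, 16000) is w

    def test_length_ratio(self, rng):
        w = Waveform(rng.standard_normal(64000), 32000)
        out = resample(w, 16000)
        assert out.rate == 16000 and len(out) == 32000

    def test_tone_survives(self):
        w = _tone(1000, 1.0, 32000)
        out = resample(w, 16000)
        spec = np.abs(np.fft.rfft(out.samples))
        freq = np.fft.rfftfreq(len(out), 1 / 16000)
        assert freq[np.argmax(spec)] == pytest.approx(1000, abs=2)


class TestComputeGain:
    def test_equal_energy_q0(self, rng):
        s = rng.standard_normal(64)
        assert compute_gain(_wave(s), _wave(s[::-1].copy()), 0.0) == pytest.approx(1.0)

    def test_closed_form(self):
        # energies 4 and 1 at q=10 dB: alpha = sqrt(4 / (10 * 1)) = 0.63246
        s1 = _wave([2.0, 0.0, 0.0, 0.0])
        s2 = _wave([1.0, 0.0, 0.0, 0.0])
        alpha = compute_gain(s1, s2, 10.0)
        assert alpha == pytest.approx(0.6324555, abs=1e-6)
        ratio_db = 10 * np.log10(s1.energy() / (alpha**2 * s2.energy()))
        assert ratio_db == pytest.approx(10.0, abs=1e-9)

    def test_silent_source_rejected(self):
        with pytest.raises(ValueError, match="zero energy"):
            compute_gain(_wave([1.0, 2.0]), _wave([0.0, 0.0]), 0.0)


class TestMixPair:
    def test_orthogonal_unit_energy_doubles(self):
        s1 = _wave([1.0, 0.0])
        s2 = _wave([0.0, 1.0])
        e = mix_pair(s1, s2, 0.0)
        assert e.mixture.energy() == pytest.approx(2.0)

    def test_mixture_is_exact_sum(self, rng):
        s1 = _wave(rng.standard_normal(1000))
        s2 = _wave(rng.standard_normal(1000))
        e = mix_pair(s1, s2, 3.3)
        assert e.residual() == 0.0

    def test_level_contract(self, rng):
        s1 = _wave(rng.standard_normal(1000))
        s2 = _wave(rng.standard_normal(1000))
        e = mix_pair(s1, s2, -4.2)
        measured = 10 * np.log10(e.sources[0].energy() / e.sources[1].energy())
        assert measured == pytest.approx(-4.2, abs=1e-6)

    def test_zero_source_rejected(self, rng):
        with pytest.raises(ValueError):
            mix_pair(_wave(rng.standard_normal(8)), _wave(np.zeros(8)), 0.0)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mix_pair(_wave(rng.standard_normal(8)), _wave(rng.standard_normal(9)), 0.0)


class TestAddNoise:
    def test_unit_gain_at_0db(self, rng):
        x = _wave(rng.standard_normal(512))
        n = _wave(np.roll(x.samples, 100))
        out = add_noise_at_snr(x, n, 0.0)
        np.testing.assert_allclose(out.samples, x.samples + n.samples, atol=1e-12)

    @pytest.mark.parametrize("snr,g_expected", [(20.0, 0.1), (10.0, 10**-0.5)])
    def test_closed_form_gain(self, rng, snr, g_expected):
        # equal energies: 10*log10(1/g^2) = snr  =>  g = 10^(-snr/20)
        x = _wave(rng.standard_normal(512))
        n = _wave(np.roll(x.samples, 7))  # equal energy
        out = add_noise_at_snr(x, n, snr)
        g = (out.samples - x.samples) / n.samples
        np.testing.assert_allclose(g, g_expected, atol=1e-9)

    def test_silent_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            add_noise_at_snr(_wave(rng.standard_normal(8)), _wave(np.zeros(8)), 5.0)


class TestNormalizeExample:
    def test_peak_factor(self, rng):
        s1 = _wave(rng.standard_normal(256))
        s2 = _wave(rng.standard_normal(256))
        e = mix_pair(s1, s2, 0.0)
        scale = 2.5 / e.mixture.peak()
        from dataclasses import replace

        e = replace(
            e,
            mixture=_wave(e.mixture.samples * scale),
            sources=[_wave(s.samples * scale) for s in e.sources],
        )
        out = normalize_example(e)
        assert out.mixture.peak() == pytest.approx(1.0)
        assert out.normalization_factor == pytest.approx(0.4)
        assert out.residual() < 1e-12

    def test_si_snr_invariant_under_normalization(self, rng):
        s1 = _wave(rng.standard_normal(256))
        s2 = _wave(rng.standard_normal(256))
        e = mix_pair(s1, s2, 2.0)
        out = normalize_example(e)
        for before, after in zip(e.sources, out.sources):
            assert si_snr(e.mixture.samples, before.samples) == pytest.approx(
                si_snr(out.mixture.samples, after.samples), abs=1e-9
            )

    def test_zero_mixture_rejected(self):
        e = mix_pair(_wave([1.0, -1.0]), _wave([-1.0, 1.0]), 0.0)
        with pytest.raises(ValueError):
            normalize_example(e)


class TestBuildDataset:
    def test_reproducible(self, small_corpus):
        m1, e1 = build_dataset(small_corpus, 5, seed=42)
        m2, e2 = build_dataset(small_corpus, 5, seed=42)
        assert m1.records == m2.records
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.mixture.samples, b.mixture.samples)

    def test_species_differ_and_additivity(self, small_corpus):
        _, examples = build_dataset(small_corpus, 40, seed=1)
        for e in examples:
            assert e.species[0] != e.species[1]
            assert e.residual() < 1e-12

    def test_q_distribution(self, small_corpus):
        _, examples = build_dataset(small_corpus, 400, noise_snr_range=None, seed=2)
        qs = np.array([e.q for e in examples])
        assert qs.min() >= -5.0 and qs.max() <= 5.0
        se = 10.0 / np.sqrt(12) / np.sqrt(len(qs))
        assert abs(qs.mean()) < 3 * se

    def test_noise_snr_recorded(self, small_corpus):
        _, examples = build_dataset(small_corpus, 10, noise_snr_range=(0, 25), seed=3)
        for e in examples:
            assert 0.0 <= e.noise_snr <= 25.0
            assert e.noise is not None

    def test_bad_count_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            build_dataset(small_corpus, 0, seed=0)

    def test_roundtrip_through_wav(self, small_corpus, tmp_path):
        manifest, examples = build_dataset(
            small_corpus, 3, noise_snr_range=None, seed=4, out_dir=tmp_path
        )
        loaded = load_examples(tmp_path / "manifest.jsonl")
        assert len(loaded) == 3
        for orig, back in zip(examples, loaded):
            # 16-bit quantization: agreement to one LSB
            np.testing.assert_allclose(
                orig.mixture.samples, back.mixture.samples, atol=1.5 / 32768
            )
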