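"""Separation quality metrics and the permutation-invariant objective.

SI-SNR (scale-invariant signal-to-noise ratio) projects the estimate onto
the reference,

    s_target = <est, ref> / ||ref||^2 * ref,
    e_noise  = est - s_target,
    SI-SNR   = 10 log10(||s_target||^2 / ||e_noise||^2),

so rescaling the estimate cannot change the score.  Signals are mean-
centered first (the convention of the metric's origin); ``zero_mean=False``
evaluates the raw projection form.  Degenerate ratios are capped at
±300 dB so downstream losses stay finite.

SDR follows the single-source BSS-Eval convention: the estimate is
projected onto the span of the reference and its first ``filter_len - 1``
delays (a least-squares FIR fit), and distortion is what remains.

Improvement metrics (SI-SNRi / SDRi) subtract the mixture's score from the
estimate's, averaged over sources under the best source-to-estimate
permutation.  The utterance-level permutation-invariant training (uPIT)
loss is the negative of the best-permutation mean SI-SNR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import fftconvolve

__all__ = [
    "SI_SNR_CAP",
    "SeparationScore",
    "si_snr",
    "si_snr_improvement",
    "upit_loss",
    "sdr",
    "sdr_improvement",
    "evaluate_example",
]

SI_SNR_CAP = 300.0


def _as_1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a mono waveform (T,)")
    return x


def _ratio_db(num: float, den: float) -> float:
    """10*log10(num/den), capped at ±SI_SNR_CAP; degenerate 0/0 scores 0."""
    if num <= 0 and den <= 0:
        return 0.0
    if num <= 0:
        return -SI_SNR_CAP
    if den <= 0:
        return SI_SNR_CAP
    return float(np.clip(10 * np.log10(num / den), -SI_SNR_CAP, SI_SNR_CAP))


def si_snr(est, ref, zero_mean: bool = True) -> float:
    """Scale-invariant SNR of `est` against reference `ref`, in dB."""
    est, ref = _as_1d(est), _as_1d(ref)
    if est.shape != ref.shape:
        raise ValueError("estimate and reference must have equal length")
    if zero_mean:
        est = est - est.mean()
        ref = ref - ref.mean()
    ref_energy = float(ref @ ref)
    if ref_energy == 0:
        raise ValueError("reference signal is zero")
    s_target = (float(est @ ref) / ref_energy) * ref
    e_noise = est - s_target
    return _ratio_db(float(s_target @ s_target), float(e_noise @ e_noise))


def _best_permutation(ests, refs, metric) -> tuple[tuple[int, ...], float]:
    """Permutation maximizing the mean metric(est_i, ref_perm[i])."""
    C = len(ests)
    best_perm, best_val = None, -np.inf
    for perm in permutations(range(C)):
        val = np.mean([metric(ests[i], refs[perm[i]]) for i in range(C)])
        if val > best_val:
            best_perm, best_val = perm, float(val)
    return best_perm, best_val


def si_snr_improvement(ests, refs, mixture, zero_mean: bool = True,
                       printed_baseline: bool = False) -> float:
    """Mean SI-SNRi over sources under the best permutation.

    The baseline is SI-SNR(mixture, ref) — how well the unprocessed mixture
    already scores against each reference.  ``printed_baseline=True``
    instead subtracts SI-SNR(est, mixture) (argument order as sometimes
    printed), for comparison.
    """
    if len(ests) != len(refs):
        raise ValueError("need as many estimates as references")
    metric = lambda e, r: si_snr(e, r, zero_mean)
    perm, _ = _best_permutation(ests, refs, metric)
    deltas = []
    for i, p in enumerate(perm):
        base = (si_snr(ests[i], mixture, zero_mean) if printed_baseline
                else si_snr(mixture, refs[p], zero_mean))
        deltas.append(si_snr(ests[i], refs[p], zero_mean) - base)
    return float(np.mean(deltas))


def upit_loss(ests, refs, zero_mean: bool = True) -> tuple[float, tuple[int, ...]]:
    """Negative best-permutation mean SI-SNR, and the best permutation."""
    if len(ests) != len(refs):
        raise ValueError("need as many estimates as references")
    metric = lambda e, r: si_snr(e, r, zero_mean)
    perm, val = _best_permutation(ests, refs, metric)
    return -val, perm


def sdr(est, ref, filter_len: int = 512) -> float:
    """BSS-Eval-style SDR: distortion is the residual of a least-squares fit
    of `est` by `ref` filtered with a `filter_len`-tap FIR."""
    est, ref = _as_1d(est), _as_1d(ref)
    if est.shape != ref.shape:
        raise ValueError("estimate and reference must have equal length")
    if len(est) <= filter_len:
        raise ValueError(f"signals must be longer than filter_len={filter_len}")
    if float(ref @ ref) == 0:
        raise ValueError("reference signal is zero")
    # project over the zero-padded support (length n + filter_len - 1), so
    # the Gram matrix of delayed references is exactly Toeplitz in the
    # full correlation sequence
    n_ext = len(ref) + filter_len - 1
    n_fft = int(2 ** np.ceil(np.log2(n_ext)))
    rf = np.fft.rfft(ref, n_fft)
    ef = np.fft.rfft(est, n_fft)
    acorr = np.fft.irfft(rf * np.conj(rf), n_fft)[:filter_len].copy()
    xcorr = np.fft.irfft(ef * np.conj(rf), n_fft)[:filter_len]
    # tiny jitter guards Levinson recursion against singular (narrow-band)
    # references; relative 1e-12 is far below the 1e-6 dB test tolerances
    acorr[0] += 1e-12 * max(acorr[0], 1e-300)
    h = solve_toeplitz((acorr, acorr.copy()), xcorr)
    s_target = fftconvolve(ref, h)  # full length n_ext
    est_ext = np.concatenate([est, np.zeros(filter_len - 1)])
    e_dist = est_ext - s_target
    return _ratio_db(float(s_target @ s_target), float(e_dist @ e_dist))


def sdr_improvement(ests, refs, mixture, filter_len: int = 512) -> float:
    """Mean SDRi over sources under the best permutation."""
    if len(ests) != len(refs):
        raise ValueError("need as many estimates as references")
    metric = lambda e, r: sdr(e, r, filter_len)
    perm, _ = _best_permutation(ests, refs, metric)
    return float(
        np.mean(
            [
                sdr(ests[i], refs[p], filter_len) - sdr(mixture, refs[p], filter_len)
                for i, p in enumerate(perm)
            ]
        )
    )


@dataclass
class SeparationScore:
    """Per-example scores under the best source-to-estimate permutation."""

    si_snr: list[float]
    sdr: list[float]
    si_snri: float
    sdri: float
    best_permutation: tuple[int, ...]


def evaluate_example(ests, refs, mixture, filter_len: int = 512) -> SeparationScore:
    perm, _ = _best_permutation(ests, refs, si_snr)
    per_si = [si_snr(ests[i], refs[p]) for i, p in enumerate(perm)]
    per_sdr = [sdr(ests[i], refs[p], filter_len) for i, p in enumerate(perm)]
    return SeparationScore(
        si_snr=per_si,
        sdr=per_sdr,
        si_snri=si_snr_improvement(ests, refs, mixture),
        sdri=sdr_improvement(ests, refs, mixture, filter_len),
        best_permutation=perm,
    )
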