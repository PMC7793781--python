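"""Spectral power and signal-regularity features on clean 6-s epochs.

Power spectral density uses Thomson's multitaper estimator: 7 Slepian
tapers (time-half-bandwidth product nw = 4), 4096-point FFT, eigenspectra
averaged unweighted, scaled as a one-sided density so the integral over
[0, f_s/2] equals the signal variance; the returned grid is restricted to
1–50 Hz.

Sample Entropy (SampEn) follows the Richman–Moorman convention: with
Chebyshev distance and tolerance r = 0.2·SD of the window, B counts pairs
of length-m templates within r and A the same for length-(m+1) templates,
both over template indices 1..N−m with self-matches excluded;
SampEn = −ln(A/B).  Zero matches yield NaN (undefined), never ±inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft
from scipy.signal import windows

from .preprocess import CleanEpochSet
from .sessions import CHANNELS, EEG_RATE

DEFAULT_NW = 4.0
DEFAULT_NFFT = 4096
DEFAULT_M = 2
DEFAULT_R_FACTOR = 0.2
PSD_BAND = (1.0, 50.0)


@dataclass
class PsdResult:
    """Session-mean one-sided PSD per channel, in μV²/Hz, on 1–50 Hz."""

    freqs: np.ndarray
    psd: np.ndarray  # (4, F)
    n_epochs: int
    channel_names: tuple[str, ...] = CHANNELS


@dataclass
class SampEnResult:
    """Session-mean Sample Entropy per channel with the parameters used."""

    values: np.ndarray  # (4,), NaN where undefined for every epoch
    n_epochs: int
    n_undefined: np.ndarray  # (4,) epochs excluded per channel
    m: int = DEFAULT_M
    r_factor: float = DEFAULT_R_FACTOR
    channel_names: tuple[str, ...] = CHANNELS


def multitaper_psd(
    x: np.ndarray,
    fs: float = EEG_RATE,
    nw: float = DEFAULT_NW,
    nfft: int = DEFAULT_NFFT,
    fband: tuple[float, float] | None = PSD_BAND,
) -> tuple[np.ndarray, np.ndarray]:
    """Thomson multitaper PSD of one epoch channel.

    Returns ``(freqs, psd)`` restricted to ``fband`` (pass ``None`` for the
    full one-sided grid, e.g. to check Parseval's identity).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    k = int(2 * nw - 1)
    if n < 2 * nw:
        raise ValueError(f"signal length {n} too short for nw={nw}")
    if nfft < n:
        raise ValueError("nfft must be >= signal length (zero-padding only)")
    tapers = windows.dpss(n, nw, Kmax=k)  # (K, N)
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))
    spectra = np.abs(rfft(tapers * x, n=nfft, axis=1)) ** 2 / fs
    psd = spectra.mean(axis=0)
    # one-sided density: double interior bins (DC and Nyquist counted once)
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.arange(psd.size) * fs / nfft
    if fband is not None:
        sel = (freqs >= fband[0]) & (freqs <= fband[1])
        freqs, psd = freqs[sel], psd[sel]
    return freqs, psd


def sampen(x: np.ndarray, m: int = DEFAULT_M,
           r_factor: float = DEFAULT_R_FACTOR) -> float:
    """Sample Entropy of a 1-D signal; NaN if undefined.

    Vectorized over the full pairwise Chebyshev distance matrix; exact
    match counts (identical to naive template counting).  Because the
    tolerance r scales with the window's SD, the result is invariant under
    affine transforms a·x + b with a > 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least m+2 = {m + 2} samples")
    sd = x.std()
    if sd == 0:
        return float("nan")
    r = r_factor * sd
    n_t = n - m  # templates of length m and m+1, indices 0..n_t-1
    diff = np.abs(x[:, None] - x[None, :])
    dm = diff[:n_t, :n_t].copy()
    for k in range(1, m):
        np.maximum(dm, diff[k:k + n_t, k:k + n_t], out=dm)
    dm1 = np.maximum(dm, diff[m:m + n_t, m:m + n_t])
    b = int((dm <= r).sum()) - n_t  # exclude self-matches
    a = int((dm1 <= r).sum()) - n_t
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def session_features(
    epochset: CleanEpochSet,
    fs: float = EEG_RATE,
    nw: float = DEFAULT_NW,
    nfft: int = DEFAULT_NFFT,
    m: int = DEFAULT_M,
    r_factor: float = DEFAULT_R_FACTOR,
) -> tuple[PsdResult, SampEnResult]:
    """Per-epoch PSD and SampEn averaged per channel across a session.

    Epochs with undefined SampEn are excluded from that channel's mean and
    counted in ``n_undefined``; a channel undefined in every epoch stays
    NaN.
    """
    if not len(epochset.epochs):
        raise ValueError("empty epoch set")
    names = tuple(epochset.channel_names) or CHANNELS
    c = epochset.epochs[0].shape[0]
    psd_acc = None
    se_sum = np.zeros(c)
    se_count = np.zeros(c, dtype=int)
    for epoch in epochset.epochs:
        for ch in range(c):
            freqs, p = multitaper_psd(epoch[ch], fs=fs, nw=nw, nfft=nfft)
            if psd_acc is None:
                psd_acc = np.zeros((c, p.size))
            psd_acc[ch] += p
            se = sampen(epoch[ch], m=m, r_factor=r_factor)
            if np.isfinite(se):
                se_sum[ch] += se
                se_count[ch] += 1
    n_ep = len(epochset.epochs)
    se_values = np.where(se_count > 0, se_sum / np.maximum(se_count, 1), np.nan)
    return (
        PsdResult(freqs=freqs, psd=psd_acc / n_ep, n_epochs=n_ep,
                  channel_names=names),
        SampEnResult(values=se_values, n_epochs=n_ep,
                     n_undefined=n_ep - se_count, m=m, r_factor=r_factor,
                     channel_names=names),
    )
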