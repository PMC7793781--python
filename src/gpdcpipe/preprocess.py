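"""Artifact removal and epoching for mobile dry-electrode EEG.

The chain runs in a fixed order: 60 Hz notch → 1–100 Hz zero-phase
Butterworth band-pass → Artifact Subspace Reconstruction (ASR) →
rule-based rejection (contact dropouts, >100 μV voltage jumps, head
acceleration above 1 m/s²) → clean 6-s epochs with 50% overlap.

Rejection operates on 250 ms subwindows.  The contact (10 Hz) and
acceleration (50 Hz) streams are upsampled to the EEG rate by zero-order
hold before thresholding.  Acceleration is made gravity-free by removing
the per-axis session median before taking the magnitude; a gravity-
inclusive magnitude (~9.8 m/s²) would trip the 1 m/s² threshold
everywhere.

ASR here is the simplified Euclidean form: calibration statistics (robust
per-component RMS location/scale over 500 ms windows, and a mixing matrix
from the eigendecomposition of the median window covariance) are computed
from the entire session; then sliding 500 ms windows with a 250 ms step
are eigendecomposed in calibration space, components whose RMS exceeds
location + cutoff×scale are zeroed, and the window is rebuilt from the
retained subspace with raised-cosine overlap-add.  A flagged component
loading almost entirely (>0.75) on a single channel marks that channel's
subwindows bad instead — with four channels, deleting a channel outright
would make the downstream 4-channel MVAR impossible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .sessions import (
    ACCEL_RATE,
    CHANNELS,
    CONTACT_RATE,
    EEG_RATE,
    SessionRecording,
)

REASONS = ("contact", "jump", "accel", "asr")


@dataclass
class PreprocConfig:
    """Every tunable of the preprocessing chain, with standard defaults."""

    notch_hz: float = 60.0
    notch_q: float = 30.0
    bandpass: tuple[float, float] = (1.0, 100.0)
    butterworth_order: int = 4
    zero_phase: bool = True
    asr_cutoff_sd: float = 10.0
    asr_window_ms: float = 500.0
    asr_step_ms: float = 250.0
    asr_loading_thresh: float = 0.75
    jump_thresh_uv: float = 100.0
    accel_thresh_ms2: float = 1.0
    min_good_contact_s: float = 60.0
    epoch_s: float = 6.0
    epoch_overlap: float = 0.5

    def __post_init__(self) -> None:
        positive = (
            self.notch_hz, self.notch_q, self.bandpass[0], self.bandpass[1],
            self.butterworth_order, self.asr_cutoff_sd, self.asr_window_ms,
            self.asr_step_ms, self.asr_loading_thresh, self.jump_thresh_uv,
            self.accel_thresh_ms2, self.min_good_contact_s, self.epoch_s,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all preprocessing parameters must be positive")
        if not 0 <= self.epoch_overlap < 1:
            raise ValueError("epoch_overlap must be in [0, 1)")
        if self.bandpass[1] >= EEG_RATE / 2:
            raise ValueError(
                f"band-pass upper edge {self.bandpass[1]} Hz must be below "
                f"Nyquist ({EEG_RATE / 2} Hz)"
            )
        if self.bandpass[0] >= self.bandpass[1]:
            raise ValueError("band-pass lower edge must be below upper edge")

    @property
    def subwindow_samples(self) -> int:
        return int(round(self.asr_step_ms / 1000.0 * EEG_RATE))

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_s * EEG_RATE))


@dataclass
class RejectionMask:
    """Per-250-ms-subwindow bad flags with reason codes, plus usability."""

    reasons: dict[str, np.ndarray]  # reason -> (n_sub,) bool, True = bad
    usable: bool
    n_subwindows: int

    @property
    def combined(self) -> np.ndarray:
        bad = np.zeros(self.n_subwindows, dtype=bool)
        for mask in self.reasons.values():
            bad |= mask
        return bad


@dataclass
class CleanEpochSet:
    """Artifact-free 6-s epochs cut from one cleaned session."""

    epochs: list[np.ndarray]  # each (4, 1320) μV
    epoch_start_samples: list[int]
    rejection_mask: RejectionMask
    kept_fraction: float
    channel_names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.epochs)


def notch_filter(eeg: np.ndarray, f0: float = 60.0, fs: float = EEG_RATE,
                 q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at the power-line frequency."""
    if f0 >= fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(f0, q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(eeg, dtype=float), axis=-1)


def bandpass_filter(eeg: np.ndarray, lo: float = 1.0, hi: float = 100.0,
                    order: int = 4, fs: float = EEG_RATE) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    if hi >= fs / 2:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist ({fs / 2} Hz)")
    if lo >= hi:
        raise ValueError("lower edge must be below upper edge")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(eeg, dtype=float), axis=-1)


def _window_starts(n: int, win: int, step: int) -> np.ndarray:
    starts = np.arange(0, n - win + 1, step)
    # cover the tail with one final window anchored at the end
    if len(starts) and starts[-1] + win < n:
        starts = np.append(starts, n - win)
    return starts


def asr_clean(
    eeg: np.ndarray, config: PreprocConfig | None = None, fs: float = EEG_RATE
) -> tuple[np.ndarray, np.ndarray]:
    """Artifact Subspace Reconstruction over sliding windows.

    Returns ``(cleaned, asr_mask)`` where ``asr_mask`` is a per-channel,
    per-250-ms-subwindow boolean array (True = channel unusable in that
    subwindow).  Deterministic: no internal randomness.
    """
    config = config or PreprocConfig()
    x = np.asarray(eeg, dtype=float)
    c, n = x.shape
    if n < config.min_good_contact_s * fs:
        raise ValueError(
            f"ASR calibration needs >= {config.min_good_contact_s:.0f} s of data"
        )
    win = int(round(config.asr_window_ms / 1000.0 * fs))
    step = int(round(config.asr_step_ms / 1000.0 * fs))
    starts = _window_starts(n, win, step)

    # --- calibration from the entire session ---
    covs = np.stack([x[:, s:s + win] @ x[:, s:s + win].T / win for s in starts])
    med_cov = np.median(covs, axis=0)
    med_cov = (med_cov + med_cov.T) / 2
    _, mix = np.linalg.eigh(med_cov)  # columns = calibration basis
    y = mix.T @ x
    win_rms = np.stack(
        [np.sqrt(np.mean(y[:, s:s + win] ** 2, axis=1)) for s in starts]
    )  # (n_windows, C)
    loc = np.median(win_rms, axis=0)
    scale = 1.4826 * np.median(np.abs(win_rms - loc), axis=0)
    scale = np.maximum(scale, 1e-12 + 1e-9 * loc)
    thresh = loc + config.asr_cutoff_sd * scale  # per calibration component

    # --- sliding-window processing ---
    n_sub = n // config.subwindow_samples
    asr_mask = np.zeros((c, n_sub), dtype=bool)
    taper = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(win) / win)  # raised cosine
    acc = np.zeros_like(x)
    wsum = np.zeros(n)
    for s in starts:
        yw = y[:, s:s + win]
        cov = yw @ yw.T / win
        evals, u = np.linalg.eigh((cov + cov.T) / 2)
        rms = np.sqrt(np.maximum(evals, 0.0))
        # threshold projected onto this window's eigendirections
        proj_thresh = np.sqrt((thresh[:, None] ** 2 * u**2).sum(axis=0))
        keep = rms <= proj_thresh
        for k in np.flatnonzero(~keep):
            loading = mix @ u[:, k]
            loading = loading / np.linalg.norm(loading)
            ch = int(np.argmax(np.abs(loading)))
            if np.abs(loading[ch]) > config.asr_loading_thresh:
                lo_sub = s // config.subwindow_samples
                hi_sub = min(int(np.ceil((s + win) / config.subwindow_samples)),
                             n_sub)
                asr_mask[ch, lo_sub:hi_sub] = True
        yc = u @ (keep[:, None] * (u.T @ yw))
        acc[:, s:s + win] += (mix @ yc) * taper
        wsum[s:s + win] += taper
    good = wsum > 1e-10
    cleaned = np.where(good, acc / np.where(good, wsum, 1.0), x)
    return cleaned, asr_mask


def _upsample_zoh(stream: np.ndarray, rate: float, n_eeg: int,
                  fs: float = EEG_RATE) -> np.ndarray:
    """Zero-order-hold a slower stream onto the EEG sample grid."""
    idx = np.minimum((np.arange(n_eeg) * rate / fs).astype(int),
                     stream.shape[-1] - 1)
    return stream[..., idx]


def rejection_mask(
    eeg: np.ndarray,
    accel: np.ndarray,
    contact: np.ndarray,
    config: PreprocConfig | None = None,
) -> RejectionMask:
    """Rule-based bad-data detection on 250 ms subwindows.

    A subwindow is bad if (a) any electrode's contact indicator differs
    from 1 (good), (b) any channel's largest absolute sample-to-sample
    voltage step exceeds the jump threshold, or (c) any gravity-free
    acceleration-magnitude sample exceeds the motion threshold.  The
    session is usable only if some contiguous all-good run spans at least
    ``min_good_contact_s``.
    """
    config = config or PreprocConfig()
    x = np.asarray(eeg, dtype=float)
    c, n = x.shape
    sub = config.subwindow_samples
    n_sub = n // sub

    contact_up = _upsample_zoh(np.asarray(contact), CONTACT_RATE, n)
    dyn = np.asarray(accel, dtype=float)
    dyn = dyn - np.median(dyn, axis=1, keepdims=True)
    accel_mag = _upsample_zoh(np.linalg.norm(dyn, axis=0), ACCEL_RATE, n)

    # assign each first difference to the subwindow of its later sample
    jumps = np.zeros(n)
    jumps[1:] = np.abs(np.diff(x, axis=1)).max(axis=0)

    contact_bad = np.zeros(n_sub, dtype=bool)
    jump_bad = np.zeros(n_sub, dtype=bool)
    accel_bad = np.zeros(n_sub, dtype=bool)
    for w in range(n_sub):
        sl = slice(w * sub, (w + 1) * sub)
        contact_bad[w] = bool((contact_up[:, sl] != 1).any())
        jump_bad[w] = bool(jumps[sl].max() > config.jump_thresh_uv)
        accel_bad[w] = bool(accel_mag[sl].max() > config.accel_thresh_ms2)

    reasons = {
        "contact": contact_bad,
        "jump": jump_bad,
        "accel": accel_bad,
        "asr": np.zeros(n_sub, dtype=bool),
    }
    combined_bad = contact_bad | jump_bad | accel_bad
    usable = _longest_good_run(~combined_bad) * sub / EEG_RATE >= (
        config.min_good_contact_s
    )
    return RejectionMask(reasons=reasons, usable=bool(usable), n_subwindows=n_sub)


def _longest_good_run(good: np.ndarray) -> int:
    best = run = 0
    for g in good:
        run = run + 1 if g else 0
        best = max(best, run)
    return best


def cut_epochs(
    eeg_cleaned: np.ndarray,
    mask: RejectionMask,
    config: PreprocConfig | None = None,
    channel_names: tuple[str, ...] = (),
) -> CleanEpochSet:
    """Cut clean fixed-length epochs on a 50%-overlap grid.

    Epoch starts lie on the hop grid (3 s for 6-s epochs at 50% overlap);
    an epoch is kept only if every covered subwindow is good, so epochs
    never span masked regions.
    """
    config = config or PreprocConfig()
    sub = config.subwindow_samples
    ep_len = config.epoch_samples
    hop = int(round(ep_len * (1 - config.epoch_overlap)))
    if hop % sub or ep_len % sub:
        raise ValueError("epoch length and hop must be whole subwindows")
    bad = mask.combined
    n = eeg_cleaned.shape[1]
    epochs, starts = [], []
    for s0 in range(0, n - ep_len + 1, hop):
        w0, w1 = s0 // sub, (s0 + ep_len) // sub
        if w1 > mask.n_subwindows or bad[w0:w1].any():
            continue
        epochs.append(eeg_cleaned[:, s0:s0 + ep_len].copy())
        starts.append(s0)
    if not epochs:
        warnings.warn("no clean epochs in session", stacklevel=2)
    n_good = int((~bad).sum())
    kept = n_good * sub / n if n else 0.0
    return CleanEpochSet(
        epochs=epochs,
        epoch_start_samples=starts,
        rejection_mask=mask,
        kept_fraction=float(kept),
        channel_names=channel_names,
    )


def preprocess_session(
    rec: SessionRecording, config: PreprocConfig | None = None
) -> CleanEpochSet:
    """Run the full chain on one session: notch → band-pass → ASR →
    rejection → epochs.  The ASR channel mask is folded into the combined
    rejection mask (all four channels are needed for the MVAR stage)."""
    config = config or PreprocConfig()
    x = notch_filter(rec.eeg, config.notch_hz, q=config.notch_q)
    x = bandpass_filter(x, *config.bandpass, order=config.butterworth_order)
    cleaned, asr_mask = asr_clean(x, config)
    mask = rejection_mask(cleaned, rec.accel, rec.contact, config)
    n_sub = mask.n_subwindows
    mask.reasons["asr"] = asr_mask[:, :n_sub].any(axis=0)
    mask.usable = bool(
        _longest_good_run(~mask.combined) * config.subwindow_samples
        / EEG_RATE >= config.min_good_contact_s
    )
    return cut_epochs(cleaned, mask, config, channel_names=CHANNELS)
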