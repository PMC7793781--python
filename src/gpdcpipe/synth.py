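"""Synthetic session generator with known ground-truth directed coupling.

Sessions are built from a stable vector-autoregressive (VAR) process — the
statistical structure the short-time MVAR/gPDC analysis assumes — and then
corrupted with the artifact classes a mobile dry-EEG preprocessing chain
must remove: 60 Hz line noise, high-amplitude motion bursts co-occurring
with accelerometer spikes, and electrode contact dropouts.

All generation is a pure function of (specification, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import windows

from .sessions import (
    ACCEL_RATE,
    CHANNELS,
    CONTACT_RATE,
    EEG_RATE,
    SessionManifest,
    SessionRecording,
    Stage,
    write_manifest,
    write_session,
)


class UnstableModelError(ValueError):
    """The requested VAR coefficients describe a non-stationary process."""


def _resolve_channel(ch: int | str, names: tuple[str, ...]) -> int:
    if isinstance(ch, str):
        try:
            return names.index(ch)
        except ValueError:
            raise ValueError(f"unknown channel {ch!r}; expected one of {names}") from None
    if not 0 <= int(ch) < len(names):
        raise ValueError(f"channel index {ch} out of range for {len(names)} channels")
    return int(ch)


@dataclass
class VarModel:
    """A VAR(p) system x(t) = Σ_k A_k x(t−k) + ε(t), ε ~ N(0, Σ).

    ``coeffs[k-1][i, j]`` is the influence of channel j at lag k on channel
    i.  Stability (companion-matrix spectral radius < 1) and symmetric
    positive-definiteness of Σ are enforced on construction.
    """

    coeffs: np.ndarray  # (p, C, C)
    noise_cov: np.ndarray  # (C, C)
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError(f"coeffs must be (p, C, C), got {self.coeffs.shape}")
        c = self.coeffs.shape[1]
        if self.noise_cov.shape != (c, c):
            raise ValueError("noise_cov shape does not match coeffs")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        try:
            np.linalg.cholesky(self.noise_cov)
        except np.linalg.LinAlgError:
            raise ValueError("noise_cov must be positive-definite") from None
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise UnstableModelError(
                f"VAR model is unstable: companion spectral radius {rho:.4f} >= 1"
            )

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def spectral_radius(self) -> float:
        p, c, _ = self.coeffs.shape
        companion = np.zeros((p * c, p * c))
        companion[:c] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            companion[c:, : (p - 1) * c] = np.eye((p - 1) * c)
        return float(np.abs(np.linalg.eigvals(companion)).max())


def make_var_model(
    edges: list[tuple] = (),
    base_diag: float = 0.5,
    order: int = 1,
    noise_sd: float | np.ndarray = 1.0,
    n_channels: int = 4,
    channel_names: tuple[str, ...] | None = None,
) -> VarModel:
    """Build a VAR model from a list of directed edges.

    ``edges`` entries are ``(source, target, strength)`` or
    ``(source, target, strength, lag)``; channels may be names or indices.
    ``A_1`` carries ``base_diag`` on its diagonal; all other coefficients
    are zero unless an edge specifies them.
    """
    names = channel_names or (CHANNELS if n_channels == 4
                              else tuple(f"ch{i}" for i in range(n_channels)))
    if len(names) != n_channels:
        raise ValueError("channel_names length must equal n_channels")
    if order < 1:
        raise ValueError("order must be >= 1")
    coeffs = np.zeros((order, n_channels, n_channels))
    coeffs[0][np.diag_indices(n_channels)] = base_diag
    for edge in edges:
        if len(edge) == 3:
            src, tgt, strength = edge
            lag = 1
        else:
            src, tgt, strength, lag = edge
        if not 1 <= lag <= order:
            raise ValueError(f"edge lag {lag} outside 1..{order}")
        i = _resolve_channel(tgt, names)
        j = _resolve_channel(src, names)
        coeffs[lag - 1, i, j] = strength
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_channels,))
    if (sd <= 0).any():
        raise ValueError("noise_sd must be positive")
    return VarModel(coeffs=coeffs, noise_cov=np.diag(sd**2),
                    channel_names=tuple(names))


def simulate_var(
    model: VarModel, n_samples: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Simulate ``n_samples`` observations from a stable VAR model.

    The first ``10 * p`` burn-in samples (beyond the requested length) are
    discarded so the output is effectively stationary.  Deterministic for a
    given seed.
    """
    p, c = model.order, model.n_channels
    if n_samples <= 10 * p:
        raise ValueError(f"n_samples must exceed 10*p = {10 * p}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    burn = 10 * p
    total = n_samples + burn
    eps = rng.multivariate_normal(
        np.zeros(c), model.noise_cov, size=total, method="cholesky"
    )
    x = np.zeros((total + p, c))
    for t in range(p, total + p):
        acc = eps[t - p]
        for k in range(p):
            acc = acc + model.coeffs[k] @ x[t - 1 - k]
        x[t] = acc
    return x[p + burn:].T.copy()


@dataclass
class ArtifactPlan:
    """Placement and amplitude of the artifact classes added to a session.

    ``burst_times`` are (start_s, duration_s) intervals of amplitude-
    modulated noise on the EEG with a co-occurring accelerometer spike;
    ``dropout_times`` are (electrode_index, start_s, duration_s) intervals
    during which the contact indicator reads bad (3).
    """

    burst_times: list[tuple[float, float]] = field(default_factory=list)
    burst_amp_uv: float = 0.0
    burst_accel_ms2: float = 0.0
    line_noise_uv: float = 0.0
    dropout_times: list[tuple[int, float, float]] = field(default_factory=list)
    burst_channels: tuple[int, ...] | None = None  # None = all channels

    def __post_init__(self) -> None:
        for amp in (self.burst_amp_uv, self.burst_accel_ms2, self.line_noise_uv):
            if amp < 0:
                raise ValueError("artifact amplitudes must be >= 0")

    def validate_against(self, duration_s: float) -> None:
        for start, dur in self.burst_times:
            if start < 0 or dur <= 0 or start + dur > duration_s:
                raise ValueError(
                    f"burst interval ({start}, {dur}) outside 0..{duration_s} s"
                )
        for _elec, start, dur in self.dropout_times:
            if start < 0 or dur <= 0 or start + dur > duration_s:
                raise ValueError(
                    f"dropout interval ({start}, {dur}) outside 0..{duration_s} s"
                )


def _burst_envelope(n: int) -> np.ndarray:
    # Tukey taper: brief cosine ramps, flat at full amplitude in between, so
    # nearly the whole nominal interval carries the artifact.
    return windows.tukey(n, alpha=0.1)


def artifact_sample_mask(plan: ArtifactPlan, duration_s: float,
                         fs: float = EEG_RATE) -> np.ndarray:
    """Boolean mask at EEG rate of samples inside planted burst intervals."""
    n = int(round(duration_s * fs))
    mask = np.zeros(n, dtype=bool)
    for start, dur in plan.burst_times:
        mask[int(round(start * fs)): int(round((start + dur) * fs))] = True
    return mask


def generate_session(
    model: VarModel,
    duration_s: float,
    plan: ArtifactPlan,
    stage: Stage | str,
    seed: int | np.random.Generator,
    session_id: str = "S000",
    participant_id: str = "P000",
    eeg_rms_uv: float = 20.0,
    accel_jitter_ms2: float = 0.1,
) -> SessionRecording:
    """Generate one synthetic session at the headset's native rates.

    The VAR output is rescaled to a per-channel RMS of ``eeg_rms_uv`` before
    line noise and bursts are added, keeping the downstream 100 μV jump
    threshold meaningful.  Acceleration is dynamic only (gravity excluded):
    Gaussian jitter plus spikes during bursts.  Contact reads 1 everywhere
    except 3 inside dropout intervals.
    """
    if duration_s < 66:
        raise ValueError("duration_s must be >= 66 (one clean minute plus edges)")
    plan.validate_against(duration_s)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_e = int(round(duration_s * EEG_RATE))
    n_a = int(round(duration_s * ACCEL_RATE))
    n_c = int(round(duration_s * CONTACT_RATE))

    eeg = simulate_var(model, n_e, rng)
    rms = np.sqrt(np.mean(eeg**2, axis=1, keepdims=True))
    eeg = eeg / rms * eeg_rms_uv

    if plan.line_noise_uv > 0:
        t = np.arange(n_e) / EEG_RATE
        eeg = eeg + plan.line_noise_uv * np.sin(2 * np.pi * 60.0 * t)

    accel = rng.normal(0.0, accel_jitter_ms2, size=(3, n_a))
    contact = np.ones((4, n_c), dtype=int)

    channels = (plan.burst_channels if plan.burst_channels is not None
                else tuple(range(model.n_channels)))
    for start, dur in plan.burst_times:
        i0, i1 = int(round(start * EEG_RATE)), int(round((start + dur) * EEG_RATE))
        env = _burst_envelope(i1 - i0)
        for ch in channels:
            eeg[ch, i0:i1] += plan.burst_amp_uv * env * rng.normal(size=i1 - i0)
        a0, a1 = int(round(start * ACCEL_RATE)), int(round((start + dur) * ACCEL_RATE))
        accel[0, a0:a1] += plan.burst_accel_ms2 * _burst_envelope(a1 - a0)

    for elec, start, dur in plan.dropout_times:
        c0, c1 = int(round(start * CONTACT_RATE)), int(round((start + dur) * CONTACT_RATE))
        contact[int(elec), c0:c1] = 3

    return SessionRecording(
        session_id=session_id,
        participant_id=participant_id,
        stage=stage,
        eeg=eeg,
        accel=accel,
        contact=contact,
    )


def make_stage_cohort(
    n_sessions_per_stage: int,
    prep_model: VarModel,
    gen_model: VarModel,
    out_dir: str | Path,
    seed: int,
    duration_s: float = 90.0,
    plan: ArtifactPlan | None = None,
    prep_edges: list[tuple] = (),
    gen_edges: list[tuple] = (),
) -> tuple[SessionManifest, pd.DataFrame]:
    """Write a two-stage cohort of synthetic sessions to disk.

    One Preparation and one Generation model; per-session seeds are spawned
    deterministically from the master seed.  Returns the manifest (also
    written as ``manifest.csv``) and a ground-truth edge table (written as
    ``ground_truth.csv`` with columns stage,source,target,strength,lag).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = plan or ArtifactPlan()
    child_seeds = np.random.SeedSequence(seed).generate_state(
        2 * n_sessions_per_stage, dtype=np.uint32
    )
    rows = []
    k = 0
    for stage, model in ((Stage.PREPARATION, prep_model),
                         (Stage.GENERATION, gen_model)):
        for i in range(n_sessions_per_stage):
            sid = f"{stage.value[:4].lower()}{i:03d}"
            rec = generate_session(
                model, duration_s, plan, stage, int(child_seeds[k]),
                session_id=sid, participant_id=f"P{i:03d}",
            )
            k += 1
            paths = write_session(rec, out_dir)
            rows.append({
                "session_id": sid,
                "participant_id": rec.participant_id,
                "stage": stage.value,
                "eeg_file": paths[0].name,
                "accel_file": paths[1].name,
                "contact_file": paths[2].name,
                "duration_s": rec.duration_s,
            })
    manifest = SessionManifest(pd.DataFrame(rows))
    write_manifest(manifest, out_dir / "manifest.csv")

    gt_rows = []
    for stage, model, edges in (
        (Stage.PREPARATION, prep_model, prep_edges),
        (Stage.GENERATION, gen_model, gen_edges),
    ):
        for edge in edges:
            src, tgt, strength = edge[:3]
            lag = edge[3] if len(edge) > 3 else 1
            names = model.channel_names
            gt_rows.append({
                "stage": stage.value,
                "source": names[_resolve_channel(src, names)],
                "target": names[_resolve_channel(tgt, names)],
                "strength": strength,
                "lag": lag,
            })
    ground_truth = pd.DataFrame(
        gt_rows, columns=["stage", "source", "target", "strength", "lag"]
    )
    ground_truth.to_csv(out_dir / "ground_truth.csv", index=False,
                        lineterminator="\n")
    return manifest, ground_truth
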