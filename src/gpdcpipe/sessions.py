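"""Session data model and file I/O for 4-channel mobile EEG recordings.

A recording session bundles three synchronized streams from a dry-electrode
headband: EEG (4 channels, 220 Hz, μV), head acceleration (3 axes, 50 Hz,
m/s²) and a per-electrode contact-quality indicator (10 Hz; 1 = good,
2 = acceptable, ≥3 = bad).  Streams are aligned by sample index from a
common session start; there are no per-sample clocks.

On-disk format is one CSV per stream plus a manifest CSV listing sessions.
Floats are serialized with Python's shortest round-trip repr, so a
write/read cycle reproduces arrays bit-for-bit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EEG_RATE = 220.0
ACCEL_RATE = 50.0
CONTACT_RATE = 10.0

#: Fixed channel order, left to right across the scalp.
CHANNELS = ("TP09", "AF07", "AF08", "TP10")
ACCEL_AXES = ("ax", "ay", "az")
CONTACT_COLS = tuple(f"cq_{ch}" for ch in CHANNELS)

MANIFEST_COLUMNS = (
    "session_id",
    "participant_id",
    "stage",
    "eeg_file",
    "accel_file",
    "contact_file",
    "duration_s",
)


class FormatError(ValueError):
    """A session or manifest file does not conform to the expected dialect."""


class Stage(str, enum.Enum):
    PREPARATION = "Preparation"
    GENERATION = "Generation"

    @classmethod
    def parse(cls, value: "Stage | str") -> "Stage":
        if isinstance(value, Stage):
            return value
        try:
            return cls(value)
        except ValueError:
            raise FormatError(
                f"unknown stage {value!r}: expected one of "
                f"{[s.value for s in cls]}"
            ) from None


@dataclass
class SessionRecording:
    """One recording session: multirate raw streams plus metadata.

    Invariants are checked on construction: fixed channel order and shapes,
    integer contact codes ≥ 1, no NaNs in the EEG, and stream durations that
    agree within one sample period of the slower stream.
    """

    session_id: str
    participant_id: str
    stage: Stage
    eeg: np.ndarray  # (4, T_e) μV at 220 Hz, order CHANNELS
    accel: np.ndarray  # (3, T_a) m/s² at 50 Hz
    contact: np.ndarray  # (4, T_c) integer indicator at 10 Hz
    start_time: str = ""

    def __post_init__(self) -> None:
        self.stage = Stage.parse(self.stage)
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.contact = np.asarray(self.contact)
        if self.eeg.ndim != 2 or self.eeg.shape[0] != len(CHANNELS):
            raise ValueError(f"eeg must be (4, T), got {self.eeg.shape}")
        if self.accel.ndim != 2 or self.accel.shape[0] != len(ACCEL_AXES):
            raise ValueError(f"accel must be (3, T), got {self.accel.shape}")
        if self.contact.ndim != 2 or self.contact.shape[0] != len(CHANNELS):
            raise ValueError(f"contact must be (4, T), got {self.contact.shape}")
        if self.eeg.shape[1] == 0:
            raise ValueError("zero-length recording rejected")
        if np.isnan(self.eeg).any():
            raise ValueError("eeg contains NaNs")
        if not np.all(np.equal(np.mod(self.contact, 1), 0)):
            raise ValueError("contact indicator must be integer-valued")
        self.contact = self.contact.astype(int)
        if (self.contact < 1).any():
            raise ValueError("contact indicator values must be >= 1")
        d_e = self.eeg.shape[1] / EEG_RATE
        d_a = self.accel.shape[1] / ACCEL_RATE
        d_c = self.contact.shape[1] / CONTACT_RATE
        if abs(d_e - d_a) > 1.0 / ACCEL_RATE + 1e-9:
            raise ValueError(
                f"EEG ({d_e:.3f} s) and accel ({d_a:.3f} s) durations disagree"
            )
        if abs(d_e - d_c) > 1.0 / CONTACT_RATE + 1e-9:
            raise ValueError(
                f"EEG ({d_e:.3f} s) and contact ({d_c:.3f} s) durations disagree"
            )

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / EEG_RATE

    @property
    def n_eeg_samples(self) -> int:
        return self.eeg.shape[1]


@dataclass
class SessionManifest:
    """Table of sessions: ids, stage labels, stream file paths, durations."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.rows.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        self.rows = self.rows[list(MANIFEST_COLUMNS)].reset_index(drop=True)
        dupes = self.rows["session_id"][self.rows["session_id"].duplicated()]
        if len(dupes):
            raise FormatError(
                f"duplicate session_id values: {sorted(set(dupes))}"
            )
        for s in self.rows["stage"]:
            Stage.parse(s)

    def __len__(self) -> int:
        return len(self.rows)


def _read_stream(path: Path, columns: tuple[str, ...]) -> np.ndarray:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    expected = ["time_s", *columns]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    data = df[list(columns)]
    for col in columns:
        if not np.issubdtype(data[col].dtype, np.number):
            bad = data[col][pd.to_numeric(data[col], errors="coerce").isna()]
            line = bad.index[0] + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric value in {col!r} at line {line}")
        if data[col].isna().any():
            line = int(data[col][data[col].isna()].index[0]) + 2
            raise FormatError(f"{path}: missing value in {col!r} at line {line}")
    return data.to_numpy().T


def read_session(
    eeg_file: str | Path,
    accel_file: str | Path,
    contact_file: str | Path,
    session_id: str,
    participant_id: str,
    stage: Stage | str,
    start_time: str = "",
) -> SessionRecording:
    """Load one session from its three stream CSVs.

    Raises :class:`FormatError` naming the offending file for missing
    columns, non-numeric cells, or stream durations disagreeing by more
    than one sample period.
    """
    eeg = _read_stream(Path(eeg_file), CHANNELS)
    accel = _read_stream(Path(accel_file), ACCEL_AXES)
    contact = _read_stream(Path(contact_file), CONTACT_COLS)
    try:
        return SessionRecording(
            session_id=session_id,
            participant_id=participant_id,
            stage=stage,
            eeg=eeg,
            accel=accel,
            contact=contact,
            start_time=start_time,
        )
    except ValueError as exc:
        raise FormatError(
            f"session {session_id!r} ({eeg_file}, {accel_file}, "
            f"{contact_file}): {exc}"
        ) from exc


def write_session(
    rec: SessionRecording, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write one session as three CSVs; returns (eeg, accel, contact) paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tag, cols, rate, data in (
        ("eeg", CHANNELS, EEG_RATE, rec.eeg),
        ("accel", ACCEL_AXES, ACCEL_RATE, rec.accel),
        ("contact", CONTACT_COLS, CONTACT_RATE, rec.contact),
    ):
        path = out_dir / f"{rec.session_id}_{tag}.csv"
        df = pd.DataFrame(data.T, columns=list(cols))
        df.insert(0, "time_s", np.arange(data.shape[1]) / rate)
        df.to_csv(path, index=False, lineterminator="\n")
        paths.append(path)
    return tuple(paths)


def read_manifest(path: str | Path) -> SessionManifest:
    """Read a manifest CSV; stream paths are resolved against its directory."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"session_id": str, "participant_id": str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    manifest = SessionManifest(df)
    base = path.parent
    for col in ("eeg_file", "accel_file", "contact_file"):
        for f in manifest.rows[col]:
            p = Path(f)
            if not (p if p.is_absolute() else base / p).exists():
                raise FormatError(f"{path}: referenced file not found: {f}")
    return manifest


def write_manifest(manifest: SessionManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.rows.to_csv(path, index=False, lineterminator="\n")
    return path


def load_session(manifest: SessionManifest, session_id: str,
                 base_dir: str | Path = ".") -> SessionRecording:
    """Load one session referenced by the manifest."""
    row = manifest.rows[manifest.rows["session_id"] == session_id]
    if row.empty:
        raise KeyError(f"session {session_id!r} not in manifest")
    row = row.iloc[0]
    base = Path(base_dir)
    return read_session(
        base / row["eeg_file"],
        base / row["accel_file"],
        base / row["contact_file"],
        session_id=row["session_id"],
        participant_id=row["participant_id"],
        stage=row["stage"],
    )


def participant_yield_percent(n_enrolled: int, n_discarded: int) -> float:
    """Percentage of enrolled participants whose data survive screening.

    Rounded to the nearest whole percent, as reported in cohort summaries
    (e.g. 18 enrolled with 11 discarded → 39%).
    """
    if n_enrolled <= 0:
        raise ValueError("n_enrolled must be positive")
    if not 0 <= n_discarded <= n_enrolled:
        raise ValueError("n_discarded must be between 0 and n_enrolled")
    return float(round(100.0 * (n_enrolled - n_discarded) / n_enrolled))
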