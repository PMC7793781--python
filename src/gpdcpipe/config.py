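"""YAML pipeline configuration: defaults, validation, normalization.

Every analysis parameter has a default matching the standard values used
throughout the package (60 Hz notch; 1–100 Hz 4th-order zero-phase
band-pass; ASR cutoff 10 SD with 500/250 ms windows; 100 μV jump and
1 m/s² motion thresholds; one clean minute required; 6-s epochs with 50%
overlap; MVAR order 12 on a 1–50 Hz grid; multitaper nw=4 with 4096-point
FFT; SampEn m=2, r=0.2·SD; α=0.05, no FDR).  An empty YAML file therefore
yields a fully specified configuration.  Unknown keys are rejected; type
or range errors are reported with the offending key path.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .preprocess import PreprocConfig


class ConfigError(ValueError):
    """A pipeline configuration is malformed."""


DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "paths": {
        "manifest": None,  # null → simulate a cohort instead
        "out_dir": "gpdcpipe_out",
    },
    "simulate": {
        "n_sessions_per_stage": 5,
        "duration_s": 120.0,
        "base_diag": 0.5,
        "model_order": 1,
        "noise_sd": 1.0,
        "coupling_strength": 0.4,
        # opposite dominant coupling direction per stage
        "prep_edges": [["AF07", "TP10", 0.4]],
        "gen_edges": [["TP10", "AF07", 0.4]],
        "eeg_rms_uv": 20.0,
        "line_noise_uv": 5.0,
        # artifacts near the session edges so a clean minute survives
        "burst_times": [[15.0, 1.0]],
        "burst_amp_uv": 300.0,
        "burst_accel_ms2": 3.0,
        "dropout_times": [[0, 100.0, 2.0]],
    },
    "preprocess": {
        "notch_hz": 60.0,
        "notch_q": 30.0,
        "bandpass": [1.0, 100.0],
        "butterworth_order": 4,
        "zero_phase": True,
        "asr_cutoff_sd": 10.0,
        "asr_window_ms": 500.0,
        "asr_step_ms": 250.0,
        "asr_loading_thresh": 0.75,
        "jump_thresh_uv": 100.0,
        "accel_thresh_ms2": 1.0,
        "min_good_contact_s": 60.0,
        "epoch_s": 6.0,
        "epoch_overlap": 0.5,
    },
    "connectivity": {
        "order": 12,
        "freq_lo": 1.0,
        "freq_hi": 50.0,
        "freq_step": 1.0,
    },
    "features": {
        "nw": 4.0,
        "nfft": 4096,
        "m": 2,
        "r_factor": 0.2,
    },
    "stats": {
        "alpha": 0.05,
        "fdr": False,
    },
}

_POSITIVE_KEYS = {
    "simulate.n_sessions_per_stage", "simulate.duration_s",
    "simulate.model_order", "simulate.noise_sd", "simulate.eeg_rms_uv",
    "connectivity.order", "connectivity.freq_lo", "connectivity.freq_hi",
    "connectivity.freq_step", "features.nw", "features.nfft", "features.m",
    "features.r_factor", "stats.alpha",
}


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline configuration."""

    seed: int
    paths: dict[str, Any]
    simulate: dict[str, Any]
    preprocess: PreprocConfig
    connectivity: dict[str, Any]
    features: dict[str, Any]
    stats: dict[str, Any]
    raw: dict[str, Any] = field(default_factory=dict, repr=False)

    @property
    def out_dir(self) -> Path:
        return Path(self.paths["out_dir"])


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here!r}")
        base = defaults[key]
        if isinstance(base, dict):
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"{here!r}: expected a mapping, got {value!r}")
            out[key] = _merge(base, value, here)
        else:
            if base is not None and value is not None and isinstance(base, bool):
                if not isinstance(value, bool):
                    raise ConfigError(f"{here!r}: expected a boolean, got {value!r}")
            elif isinstance(base, (int, float)) and base is not None:
                if not isinstance(value, (int, float)) or isinstance(value, bool):
                    raise ConfigError(f"{here!r}: expected a number, got {value!r}")
            elif isinstance(base, (list, tuple)):
                if value is not None and not isinstance(value, (list, tuple)):
                    raise ConfigError(f"{here!r}: expected a list, got {value!r}")
            out[key] = value
    return out


def normalize_config(data: dict[str, Any] | None) -> PipelineConfig:
    """Fill defaults, reject unknown keys, and range-check a config dict."""
    merged = _merge(DEFAULTS, data or {})
    for dotted in _POSITIVE_KEYS:
        section, key = dotted.split(".")
        value = merged[section][key]
        if value is not None and value <= 0:
            raise ConfigError(f"{dotted!r} must be positive, got {value!r}")
    if merged["connectivity"]["freq_lo"] >= merged["connectivity"]["freq_hi"]:
        raise ConfigError("'connectivity.freq_lo' must be below 'connectivity.freq_hi'")
    if not 0 < merged["stats"]["alpha"] < 1:
        raise ConfigError("'stats.alpha' must lie in (0, 1)")
    try:
        preproc = PreprocConfig(
            notch_hz=merged["preprocess"]["notch_hz"],
            notch_q=merged["preprocess"]["notch_q"],
            bandpass=tuple(merged["preprocess"]["bandpass"]),
            butterworth_order=merged["preprocess"]["butterworth_order"],
            zero_phase=merged["preprocess"]["zero_phase"],
            asr_cutoff_sd=merged["preprocess"]["asr_cutoff_sd"],
            asr_window_ms=merged["preprocess"]["asr_window_ms"],
            asr_step_ms=merged["preprocess"]["asr_step_ms"],
            asr_loading_thresh=merged["preprocess"]["asr_loading_thresh"],
            jump_thresh_uv=merged["preprocess"]["jump_thresh_uv"],
            accel_thresh_ms2=merged["preprocess"]["accel_thresh_ms2"],
            min_good_contact_s=merged["preprocess"]["min_good_contact_s"],
            epoch_s=merged["preprocess"]["epoch_s"],
            epoch_overlap=merged["preprocess"]["epoch_overlap"],
        )
    except ValueError as exc:
        raise ConfigError(f"'preprocess': {exc}") from exc
    return PipelineConfig(
        seed=int(merged["seed"]),
        paths=merged["paths"],
        simulate=merged["simulate"],
        preprocess=preproc,
        connectivity=merged["connectivity"],
        features=merged["features"],
        stats=merged["stats"],
        raw=merged,
    )


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and normalize a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return normalize_config(data)


def dump_resolved(config: PipelineConfig, path: str | Path) -> Path:
    """Write the fully resolved configuration next to the outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=True)
    return path
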