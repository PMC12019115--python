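"""Table formats and configuration for the pipeline.

Interchange is plain CSV: a trial table (one row per recorded trial,
including online-aborted attempts) and a long-format trajectory table
(participant_id, trial_index, t, input_x, input_y, cursor_x, cursor_y).
Angles are stored in degrees throughout. Writing then reading a table
round-trips all fields exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "TRIAL_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "write_trials",
    "read_trials",
    "write_trajectories",
    "read_trajectories",
    "default_config",
    "load_config",
    "config_hash",
]

TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "group",
    "device",
    "rotation_direction",
    "block_label",
    "trial_index",
    "schedule_index",
    "cycle_index",
    "context",
    "target_angle",
    "rotation_deg",
    "time_limit_ms",
    "outcome",
    "probe_flag",
    "return_feedback",
    "online_check",
    "gen_cycle",
    "is_repeat",
]

TRAJECTORY_COLUMNS = [
    "participant_id",
    "trial_index",
    "t",
    "input_x",
    "input_y",
    "cursor_x",
    "cursor_y",
]

_VALID_ROTATIONS = (-30.0, 0.0, 30.0)
_NUMERIC_TRAJECTORY = ["t", "input_x", "input_y", "cursor_x", "cursor_y"]


class SchemaError(ValueError):
    """A table is missing required columns or contains malformed rows."""


def _check_columns(df: pd.DataFrame, required, label: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table is missing columns: {missing}")


def write_trials(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    _check_columns(trials, TRIAL_COLUMNS, "trial")
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def read_trials(path, max_malformed_frac: float = 0.01) -> pd.DataFrame:
    """Read a trial table, validating schema and row sanity.

    Rows with a rotation outside {-30, 0, +30} or duplicated
    (participant_id, trial_index) keys are logged as malformed; more than
    ``max_malformed_frac`` of them fails the read.
    """
    df = pd.read_csv(Path(path), float_precision="round_trip")
    _check_columns(df, TRIAL_COLUMNS, "trial")
    bad = ~df["rotation_deg"].isin(_VALID_ROTATIONS)
    dup = df.duplicated(subset=["participant_id", "trial_index"], keep=False)
    malformed = bad | dup
    if malformed.any():
        frac = malformed.mean()
        if frac > max_malformed_frac:
            raise SchemaError(
                f"{malformed.sum()} malformed trial rows ({frac:.1%} > {max_malformed_frac:.0%})"
            )
        df = df[~malformed].reset_index(drop=True)
    return df


def write_trajectories(trajectories: pd.DataFrame, path) -> Path:
    path = Path(path)
    _check_columns(trajectories, TRAJECTORY_COLUMNS, "trajectory")
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectories.to_csv(path, index=False)
    return path


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    _check_columns(df, TRAJECTORY_COLUMNS, "trajectory")
    if not all(np.issubdtype(df[c].dtype, np.number) for c in _NUMERIC_TRAJECTORY):
        raise SchemaError("trajectory sample columns must be numeric")
    return df


# ---------------------------------------------------------------------------
# Run configuration


def default_config() -> dict:
    """The full default run configuration (every tunable, with units)."""
    return {
        "experiment": "exp1",
        "n_per_group": 8,
        "seed": 0,
        "output_dir": "vmadapt_out",
        "geometry": {
            "camera_distance": 10.0,  # au
            "inverted_axes": "both",
        },
        "simulation": {
            "frame_jitter": 0.1,  # fraction of the nominal frame period
            "frame_rates": [60.0, 120.0, 144.0],  # Hz, cycled over participants
            "correction": True,
        },
        "learner": {
            "retention_A": 0.99,
            "learning_rate_B": 0.08,
            "gen_sigma": 45.0,  # degrees
            "motor_noise_sd": 4.0,  # degrees
            "p_jump_start": 0.05,
            "glitch_rate": 0.003,
            "rt_limit_threshold_ms": 750.0,
            "rt_limit_slope_ms": 100.0,
        },
        "preprocessing": {
            "resample_hz": 100.0,
            "filter_order": 2,
            "cutoff_hz": 15.0,
            "glitch_threshold": 40.0,  # au/s
            "pad_samples": 24,
        },
    }


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict = None) -> dict:
    """Defaults, optionally overlaid with a YAML/JSON file and a dict."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        config = _deep_update(config, loaded)
    if overrides:
        config = _deep_update(config, overrides)
    if config["n_per_group"] < 1:
        raise ValueError("n_per_group must be at least 1")
    return config


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration, stamped into every output."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
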