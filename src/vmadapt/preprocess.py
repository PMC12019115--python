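"""Trajectory conditioning: glitch rejection, resampling, zero-phase filtering.

The stage order is fixed — glitch detection on the raw frames, linear
resampling to a uniform grid, then a zero-phase low-pass Butterworth filter
— because the glitch threshold (a speed *change* of 40 au/s between
adjacent frames) is defined on the raw sample stream and would be washed
out by interpolation or filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
__all__ = [
    "PreprocessConfig",
    "detect_glitches",
    "resample_uniform",
    "lowpass_zero_phase",
    "preprocess_trial",
    "preprocess_trials",
]

REASON_GLITCH = "glitch"
REASON_TOO_SHORT = "too-short"
REASON_NON_MONOTONE = "non-monotone"


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    The 100 Hz resampling rate, 2nd-order/15 Hz zero-phase Butterworth and
    the 40 au/s glitch threshold are the pipeline's standard analysis
    settings. ``pad_samples`` controls the odd-reflection padding applied
    around each trial before the forward-backward filter pass; it must be at
    least three times the filter order.
    """

    resample_hz: float = 100.0
    filter_order: int = 2
    cutoff_hz: float = 15.0
    glitch_threshold: float = 40.0
    pad_samples: int = 24

    def __post_init__(self):
        if self.cutoff_hz >= self.resample_hz / 2.0:
            raise ValueError("cutoff must be below the Nyquist frequency")
        if self.pad_samples < 3 * self.filter_order:
            raise ValueError("pad_samples must be >= 3 * filter_order")


def _interval_speeds(t, xy):
    dt = np.diff(t)
    return np.linalg.norm(np.diff(xy, axis=0), axis=1) / dt


def detect_glitches(samples, threshold: float = 40.0, channels=("cursor", "input")) -> bool:
    """True iff any sample's speed differs from its predecessor's or
    successor's by strictly more than ``threshold`` au/s.

    ``samples`` is an (N, 5) array of (t, input_x, input_y, cursor_x,
    cursor_y); the check runs on raw, pre-resampling frames. Both the input
    and the task-plane cursor channel are checked by default (their speeds
    coincide under a pure rotation but diverge for single-channel glitches
    and Look-context recordings of the screen cursor). Requires >= 3
    samples.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 3:
        raise ValueError("glitch detection requires at least 3 samples")
    t = samples[:, 0]
    cols = {"input": samples[:, 1:3], "cursor": samples[:, 3:5]}
    for name in channels:
        speeds = _interval_speeds(t, cols[name])
        if np.any(np.abs(np.diff(speeds)) > threshold):
            return True
    return False


def resample_uniform(samples, resample_hz: float = 100.0) -> np.ndarray:
    """Linearly interpolate all channels onto a uniform grid.

    The grid starts at the first timestamp and never extrapolates beyond
    the recorded span. Timestamps must be strictly increasing.
    """
    samples = np.asarray(samples, dtype=float)
    t = samples[:, 0]
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    n_out = int(np.floor((t[-1] - t[0]) * resample_hz + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / resample_hz
    out = np.empty((n_out, samples.shape[1]))
    out[:, 0] = grid
    for j in range(1, samples.shape[1]):
        out[:, j] = np.interp(grid, t, samples[:, j])
    return out


def lowpass_zero_phase(samples, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Zero-phase Butterworth low-pass on uniformly sampled channels.

    Equivalent to a forward-backward pass of an order-``filter_order``
    Butterworth: the net magnitude response is the squared single-pass
    magnitude, ``|H(f)|^2 = (1 + (f/fc)^(2*order))^-1``, with zero net
    phase. The gain is applied spectrally so the magnitude is exact at all
    frequencies (a time-domain bilinear-transform filter would warp the
    response toward Nyquist). The series is padded by odd reflection before
    filtering to suppress edge transients; trials shorter than the pad
    length cannot be filtered and raise ``ValueError``.
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    pad = cfg.pad_samples
    if n <= pad:
        raise ValueError("trial shorter than filter pad length")
    data = samples[:, 1:]
    top = 2.0 * data[0] - data[pad:0:-1]
    bottom = 2.0 * data[-1] - data[-2 : -pad - 2 : -1]
    ext = np.vstack([top, data, bottom])
    freqs = np.fft.rfftfreq(len(ext), d=1.0 / cfg.resample_hz)
    gain = 1.0 / (1.0 + (freqs / cfg.cutoff_hz) ** (2 * cfg.filter_order))
    filtered = np.fft.irfft(
        np.fft.rfft(ext, axis=0) * gain[:, None], n=len(ext), axis=0
    )
    out = samples.copy()
    out[:, 1:] = filtered[pad : pad + n]
    return out


def preprocess_trial(samples, cfg: PreprocessConfig = PreprocessConfig()):
    """Condition one trial; returns ``(processed, reason)``.

    ``processed`` is None when the trial is excluded, with ``reason`` one of
    the exclusion codes (glitch, too-short, non-monotone).
    """
    try:
        if detect_glitches(samples, cfg.glitch_threshold):
            return None, REASON_GLITCH
    except ValueError:
        return None, REASON_TOO_SHORT
    try:
        resampled = resample_uniform(samples, cfg.resample_hz)
    except ValueError:
        return None, REASON_NON_MONOTONE
    try:
        return lowpass_zero_phase(resampled, cfg), None
    except ValueError:
        return None, REASON_TOO_SHORT


def preprocess_trials(trajectories: pd.DataFrame, cfg: PreprocessConfig = PreprocessConfig()):
    """Condition a long-format trajectory table trial by trial.

    Returns ``(clean, exclusions)``: the conditioned table in the same
    long format and a per-trial exclusion log (participant_id, trial_index,
    reason).
    """
    clean_parts = []
    excluded = []
    cols = ["t", "input_x", "input_y", "cursor_x", "cursor_y"]
    for (pid, trial), g in trajectories.groupby(["participant_id", "trial_index"], sort=True):
        processed, reason = preprocess_trial(g[cols].to_numpy(), cfg)
        if processed is None:
            excluded.append({"participant_id": pid, "trial_index": trial, "reason": reason})
            continue
        df = pd.DataFrame(processed, columns=cols)
        df.insert(0, "trial_index", trial)
        df.insert(0, "participant_id", pid)
        clean_parts.append(df)
    clean = (
        pd.concat(clean_parts, ignore_index=True)
        if clean_parts
        else pd.DataFrame(columns=["participant_id", "trial_index"] + cols)
    )
    exclusions = pd.DataFrame(excluded, columns=["participant_id", "trial_index", "reason"])
    return clean, exclusions
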