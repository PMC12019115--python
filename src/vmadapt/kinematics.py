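"""Per-trial kinematic measures: peak speed, hand angles, validity flags.

The central measure is the *hand angle at peak speed*: the signed angle
between the start-to-target line and the start-to-input line at the moment
of peak radial speed. The input (hand) channel is used throughout — it is
unaffected by the visuomotor perturbation. A second angle at a fixed 0.2 au
radius ("take-off") catches movements launched at an uncued target before
feedback could correct them.

Sign conventions: raw angles are counter-clockwise positive. Reported
angles are normalized so that, for either perturbation direction, positive
means the hand moved opposite to the perturbation; Inverted-Look trials
additionally get a 180-degree correction so that their angles are measured
from the ideal aim location and are directly comparable with Look trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import INVERTED_LOOK, wrap_angle

__all__ = [
    "radial_speed",
    "hand_angle_at_peak",
    "hand_angle_at_radius",
    "normalize_sign",
    "correct_inverted_look",
    "classify_jump_start",
    "extract_trial",
    "extract_metrics",
]

TAKEOFF_RADIUS_AU = 0.2
JUMP_START_THRESHOLD_DEG = 60.0


class UnanalyzableTrial(ValueError):
    """The trial does not support the requested measure."""


def radial_speed(t, xy) -> np.ndarray:
    """Central-difference time derivative of distance from the start-point."""
    r = np.linalg.norm(np.asarray(xy, dtype=float), axis=1)
    return np.gradient(r, np.asarray(t, dtype=float))


def hand_angle_at_peak(t, input_xy, target_angle: float) -> float:
    """Raw signed hand angle (deg, CCW positive) at peak radial speed."""
    t = np.asarray(t, dtype=float)
    input_xy = np.asarray(input_xy, dtype=float)
    speed = radial_speed(t, input_xy)
    k = int(np.argmax(speed))
    pos = input_xy[k]
    if np.linalg.norm(pos) < 1e-9:
        raise UnanalyzableTrial("input position at peak speed is at the start-point")
    angle = np.rad2deg(np.arctan2(pos[1], pos[0]))
    return wrap_angle(angle - target_angle)


def hand_angle_at_radius(input_xy, target_angle: float, radius: float = TAKEOFF_RADIUS_AU) -> float:
    """Raw signed hand angle at the first crossing of ``radius``.

    The angle is linearly interpolated between the bracketing samples'
    target-relative angles (shortest way around the circle).
    """
    input_xy = np.asarray(input_xy, dtype=float)
    radii = np.linalg.norm(input_xy, axis=1)
    beyond = np.nonzero(radii >= radius)[0]
    if beyond.size == 0:
        raise UnanalyzableTrial(f"trajectory never crosses radius {radius}")
    k = int(beyond[0])
    a1 = wrap_angle(np.rad2deg(np.arctan2(input_xy[k, 1], input_xy[k, 0])) - target_angle)
    if k == 0:
        return a1
    a0 = wrap_angle(np.rad2deg(np.arctan2(input_xy[k - 1, 1], input_xy[k - 1, 0])) - target_angle)
    denom = radii[k] - radii[k - 1]
    frac = 0.0 if denom == 0 else (radius - radii[k - 1]) / denom
    return wrap_angle(a0 + frac * wrap_angle(a1 - a0))


def normalize_sign(raw_angle: float, rotation_direction: str) -> float:
    """Flip the sign for counter-clockwise-perturbation participants so
    positive always means 'opposite to the perturbation'."""
    if rotation_direction == "ccw":
        return -raw_angle
    if rotation_direction == "cw":
        return raw_angle
    raise ValueError(f"rotation direction must be 'cw' or 'ccw', got {rotation_direction!r}")


def correct_inverted_look(angle: float) -> float:
    """180-degree correction for Inverted-Look trials, wrapped to (-180, 180]."""
    return wrap_angle(angle + 180.0)


def classify_jump_start(
    hand_angle_peak: float,
    hand_angle_takeoff: float,
    mode: str = "offline",
    threshold: float = JUMP_START_THRESHOLD_DEG,
) -> bool:
    """Flag movements launched at an uncued target.

    ``offline`` (post hoc): both the peak-speed and take-off angles exceed
    the threshold in absolute value. ``online`` (the in-task check): the
    take-off angle alone exceeds it. Raw, pre-normalization angles are used;
    the threshold is symmetric so the choice is immaterial.
    """
    if mode == "offline":
        return abs(hand_angle_peak) > threshold and abs(hand_angle_takeoff) > threshold
    if mode == "online":
        return abs(hand_angle_takeoff) > threshold
    raise ValueError(f"unknown mode {mode!r}")


def extract_trial(t, input_xy, target_angle: float) -> dict:
    """Raw per-trial kinematics; angles are pre-normalization."""
    t = np.asarray(t, dtype=float)
    input_xy = np.asarray(input_xy, dtype=float)
    out = dict.fromkeys(
        ["peak_speed", "t_peak", "raw_angle_peak", "raw_angle_takeoff"], np.nan
    )
    out["unanalyzable"] = False
    try:
        speed = radial_speed(t, input_xy)
        k = int(np.argmax(speed))
        out["peak_speed"] = float(speed[k])
        out["t_peak"] = float(t[k])
        out["raw_angle_peak"] = hand_angle_at_peak(t, input_xy, target_angle)
        out["raw_angle_takeoff"] = hand_angle_at_radius(input_xy, target_angle)
    except (UnanalyzableTrial, ValueError):
        out["unanalyzable"] = True
    return out


def extract_metrics(
    clean_trajectories: pd.DataFrame,
    trials: pd.DataFrame,
    exclusions: pd.DataFrame = None,
) -> pd.DataFrame:
    """Per-trial metrics table for a conditioned cohort.

    Joins each trial's preprocessed samples with its metadata and computes
    peak speed, normalized hand angles (sign convention and Inverted-Look
    correction applied) and validity flags. Trials excluded during
    preprocessing appear with ``glitch=True``-style flags taken from the
    exclusion log; the overall ``valid`` flag additionally applies the
    experiment's jump-start filter (offline double-angle rule where there
    was no online check, peak-angle rule elsewhere) and drops aborted
    repeats' originals.
    """
    grouped = dict(iter(clean_trajectories.groupby(["participant_id", "trial_index"], sort=False)))
    rows = []
    for rec in trials.to_dict("records"):
        key = (rec["participant_id"], rec["trial_index"])
        row = {
            "participant_id": rec["participant_id"],
            "trial_index": rec["trial_index"],
        }
        g = grouped.get(key)
        if g is None:
            row.update(
                peak_speed=np.nan, t_peak=np.nan, raw_angle_peak=np.nan,
                raw_angle_takeoff=np.nan, unanalyzable=True,
            )
        else:
            row.update(
                extract_trial(
                    g["t"].to_numpy(),
                    g[["input_x", "input_y"]].to_numpy(),
                    rec["target_angle"],
                )
            )
        raw_peak = row["raw_angle_peak"]
        raw_takeoff = row["raw_angle_takeoff"]
        # angles relative to the ideal aim location: Inverted-Look trials
        # need the 180-degree correction before any thresholding
        if rec["context"] == INVERTED_LOOK:
            ideal_peak = correct_inverted_look(raw_peak) if np.isfinite(raw_peak) else np.nan
            ideal_takeoff = correct_inverted_look(raw_takeoff) if np.isfinite(raw_takeoff) else np.nan
        else:
            ideal_peak, ideal_takeoff = raw_peak, raw_takeoff
        if np.isfinite(raw_peak):
            hand_angle = normalize_sign(raw_peak, rec["rotation_direction"])
            if rec["context"] == INVERTED_LOOK:
                hand_angle = correct_inverted_look(hand_angle)
        else:
            hand_angle = np.nan
        offline_jump = (
            classify_jump_start(ideal_peak, ideal_takeoff, "offline")
            if np.isfinite(ideal_peak) and np.isfinite(ideal_takeoff)
            else False
        )
        # after online repeats, a residual >60 deg peak-angle filter applies
        peak_outlier = bool(np.isfinite(ideal_peak) and abs(ideal_peak) > JUMP_START_THRESHOLD_DEG)
        jump_flag = peak_outlier if rec.get("online_check", False) else offline_jump
        excluded_preproc = g is None
        row.update(
            hand_angle=hand_angle,
            jump_start=jump_flag,
            glitch=excluded_preproc,
            valid=not (jump_flag or excluded_preproc or row["unanalyzable"]
                       or rec["outcome"] == "jump_start_repeat"),
        )
        rows.append(row)
    metrics = pd.DataFrame(rows)
    if exclusions is not None and len(exclusions):
        reason = exclusions.set_index(["participant_id", "trial_index"])["reason"]
        idx = pd.MultiIndex.from_frame(metrics[["participant_id", "trial_index"]])
        metrics["exclusion_reason"] = reason.reindex(idx).to_numpy()
    else:
        metrics["exclusion_reason"] = None
    return metrics
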