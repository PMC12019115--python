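"""Synthetic trajectories and full cohorts.

Each trial's input path is a 1 au minimum-jerk reach along the executed
hand direction, optionally followed by a late corrective sub-movement that
steers the cursor onto the target (the "hooked" paths seen early in a
rotation block). Samples are emitted at a participant-specific frame rate
(~60-144 Hz) with uniform per-frame jitter, and the cursor channel is
obtained from the input channel through the context's forward mapping, so
the recorded data honour the Point/Look equivalence by construction.

Artifacts emulated:

* jump starts — movements launched at an uncued target 90 degrees away;
  where the online take-off check is active these are aborted at the 0.2 au
  radius and the trial is repeated,
* single-frame input glitches — one sample displaced far enough that the
  cursor speed changes by well over 40 au/s,
* staircase-coupled hit/timeout outcomes via a logistic observer of the
  trial time limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .geometry import ContextConfig, Rotation, TaskLayout
from .learner import LearnerParams, planned_hand_direction, simulate_learner
from .schedule import (
    Schedule,
    build_schedule,
    init_staircases,
    staircase_limit,
    update_staircase,
)

__all__ = [
    "generate_trajectory",
    "inject_artifacts",
    "generate_cohort",
    "CohortData",
    "GROUPS",
]

REACH_AMPLITUDE_AU = 1.0
REACH_DURATION_S = 0.45
CORRECTION_GAP_S = 0.05
CORRECTION_DURATION_S = 0.2
LEAD_FRAMES = 3
TAIL_FRAMES = 2
ONLINE_CHECK_RADIUS_AU = 0.2
ONLINE_CHECK_THRESHOLD_DEG = 60.0
GLITCH_SPEED_AU_S = 60.0

TRAJECTORY_COLUMNS = ["participant_id", "trial_index", "t", "input_x", "input_y", "cursor_x", "cursor_y"]

GROUPS = {
    "exp1": [("point", {"context": "point"}), ("look", {"context": "look"})],
    "exp2a": [("point_trained", {"trained_context": "point"}),
              ("look_trained", {"trained_context": "look"})],
    "exp2b": [("point_trained", {"trained_context": "point"}),
              ("look_trained", {"trained_context": "look"})],
    "exp3": [("look_probe", {"probe_context": "look"}),
             ("inverted_look_probe", {"probe_context": "inverted_look"})],
}


def _minimum_jerk(s):
    s = np.clip(s, 0.0, 1.0)
    return 10.0 * s**3 - 15.0 * s**4 + 6.0 * s**5


def _frame_times(rng, total_duration, frame_rate_hz, jitter_frac):
    period = 1.0 / frame_rate_hz
    n_max = int(np.ceil(total_duration / (period * (1.0 - jitter_frac)))) + 2
    if jitter_frac > 0:
        periods = period * (1.0 + rng.uniform(-jitter_frac, jitter_frac, size=n_max))
    else:
        periods = np.full(n_max, period)
    t = np.concatenate([[0.0], np.cumsum(periods)])
    return t[t <= total_duration + period]


def _unit(angle_deg):
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def generate_trajectory(
    executed_dir_deg: float,
    target_angle: float,
    cfg: ContextConfig,
    rot: Rotation,
    rng,
    frame_rate_hz: float = 60.0,
    frame_jitter: float = 0.1,
    duration_s: float = REACH_DURATION_S,
    correction: bool = True,
    online_check: bool = False,
    layout: TaskLayout = TaskLayout(),
):
    """Simulate one trial's sampled input and cursor paths.

    ``executed_dir_deg`` is the absolute hand-space direction of the
    movement. Returns ``(samples, stopped)`` where ``samples`` is an (N, 5)
    array of (t, input_x, input_y, cursor_x, cursor_y) and ``stopped`` is
    True when the online take-off check aborted the trial.
    """
    if not 50.0 <= frame_rate_hz <= 150.0:
        raise ValueError("frame rate must lie in [50, 150] Hz")
    u = _unit(executed_dir_deg)
    target_pos = layout.target_position(target_angle)
    # input endpoint that puts the cursor on the target (for the correction)
    q = geometry.invert_map(np.vstack([[0.0, 0.0], target_pos]), cfg, rot).sum(axis=0)

    lead = LEAD_FRAMES / frame_rate_hz
    p_end = REACH_AMPLITUDE_AU * u
    do_correction = correction and np.linalg.norm(q - p_end) > 0.05
    total = lead + duration_s + TAIL_FRAMES / frame_rate_hz
    if do_correction:
        total += CORRECTION_GAP_S + CORRECTION_DURATION_S

    t = _frame_times(rng, total, frame_rate_hz, frame_jitter)
    pos = np.zeros((len(t), 2))
    main = _minimum_jerk((t - lead) / duration_s)
    pos[:] = np.outer(main, p_end)
    if do_correction:
        tc0 = lead + duration_s + CORRECTION_GAP_S
        s2 = _minimum_jerk((t - tc0) / CORRECTION_DURATION_S)
        pos += np.outer(s2, q - p_end)

    stopped = False
    if online_check:
        ideal = planned_hand_direction(target_angle, cfg.context, cfg.inverted_axes)
        radii = np.linalg.norm(pos, axis=1)
        crossing = np.nonzero(radii >= ONLINE_CHECK_RADIUS_AU)[0]
        if crossing.size:
            k = crossing[0]
            angle = np.rad2deg(np.arctan2(pos[k, 1], pos[k, 0]))
            if abs(geometry.wrap_angle(angle - ideal)) > ONLINE_CHECK_THRESHOLD_DEG:
                stopped = True
                end = min(k + 2, len(t))
                t, pos = t[:end], pos[:end]

    fwd = geometry.forward_map(np.diff(pos, axis=0), cfg, rot)
    samples = np.column_stack([t, pos, fwd.cursor_plane])
    return samples, stopped


def inject_artifacts(samples: np.ndarray, glitch_rate: float, rng) -> np.ndarray:
    """With probability ``glitch_rate``, displace one interior sample of both
    channels by a single-frame jump large enough that the cursor speed
    changes by more than 40 au/s relative to neighbouring samples."""
    if glitch_rate <= 0 or rng.random() >= glitch_rate or len(samples) < 4:
        return samples
    out = samples.copy()
    k = int(rng.integers(1, len(out) - 1))
    dt = out[k, 0] - out[k - 1, 0]
    offset = GLITCH_SPEED_AU_S * dt * _unit(rng.uniform(0.0, 360.0))
    out[k, 1:3] += offset
    out[k, 3:5] += offset
    return out


@dataclass
class CohortData:
    """Trial metadata and long-format trajectory samples for a cohort."""

    experiment: str
    trials: pd.DataFrame
    trajectories: pd.DataFrame


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _participant_trials(
    participant_id,
    experiment,
    schedule: Schedule,
    learner_df,
    params: LearnerParams,
    device,
    rng,
    frame_rate_hz,
    frame_jitter,
    camera_distance,
    inverted_axes,
    correction,
    with_trajectories=True,
):
    """Execute one participant's schedule: outcomes, repeats, trajectories."""
    use_staircase = experiment in ("exp1", "exp2a", "exp2b")
    stair = init_staircases(device) if use_staircase else None
    threshold = params.rt_limit_threshold_ms + (330.0 if device == "trackpad" else 0.0)
    layout = TaskLayout()

    trial_rows = []
    traj_parts = []
    trial_index = 0

    sched = schedule.trials
    meta_cols = sched.to_dict("records")
    configs = {
        ctx: ContextConfig(context=ctx, camera_distance=camera_distance, inverted_axes=inverted_axes)
        for ctx in sched["context"].unique()
    }

    def record(meta, executed_dev, is_repeat, aborted):
        nonlocal trial_index, stair
        cfg = configs[meta["context"]]
        rot = Rotation.from_signed(meta["rotation_deg"])
        hand_dir = planned_hand_direction(meta["target_angle"], meta["context"], inverted_axes)
        if use_staircase:
            limit = staircase_limit(stair)
        else:
            limit = np.nan
        if aborted:
            outcome = "jump_start_repeat"
        elif use_staircase:
            success = rng.random() < _logistic((limit - threshold) / params.rt_limit_slope_ms)
            stair = update_staircase(stair, success)
            outcome = "hit" if success else "timeout"
        else:
            outcome = "hit"
        if with_trajectories:
            samples, stopped = generate_trajectory(
                hand_dir + executed_dev,
                meta["target_angle"],
                cfg,
                rot,
                rng,
                frame_rate_hz=frame_rate_hz,
                frame_jitter=frame_jitter,
                correction=correction and not aborted,
                online_check=bool(meta["online_check"]),
            )
            samples = inject_artifacts(samples, params.glitch_rate, rng)
            traj_parts.append(
                np.column_stack([np.full(len(samples), trial_index), samples])
            )
        row = dict(meta)
        row.update(
            participant_id=participant_id,
            experiment=experiment,
            device=device,
            rotation_direction=schedule.rotation_direction,
            trial_index=trial_index,
            time_limit_ms=limit,
            outcome=outcome,
            is_repeat=is_repeat,
            executed_dev_deg=executed_dev,
            aim_deg=np.nan if aborted else None,
        )
        trial_rows.append(row)
        trial_index += 1

    aims = learner_df["aim_deg"].to_numpy()
    noises = learner_df["motor_noise_deg"].to_numpy()
    executed = learner_df["executed_dev_deg"].to_numpy()
    aborted_flags = learner_df["aborted_attempt"].to_numpy()

    for i, meta in enumerate(meta_cols):
        if aborted_flags[i]:
            # aborted jump-start attempt, recorded then repeated in place
            attempt_dev = aims[i] + rng.choice([-90.0, 90.0]) + (
                rng.normal(0.0, params.motor_noise_sd) if params.motor_noise_sd > 0 else 0.0
            )
            record(meta, attempt_dev, is_repeat=False, aborted=True)
            record(meta, executed[i], is_repeat=True, aborted=False)
        else:
            record(meta, executed[i], is_repeat=False, aborted=False)
        trial_rows[-1]["aim_deg"] = aims[i]

    trials = pd.DataFrame(trial_rows)
    if with_trajectories and traj_parts:
        arr = np.vstack(traj_parts)
        traj = pd.DataFrame(arr, columns=["trial_index", "t", "input_x", "input_y", "cursor_x", "cursor_y"])
        traj["trial_index"] = traj["trial_index"].astype(int)
        traj.insert(0, "participant_id", participant_id)
    else:
        traj = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return trials, traj


def generate_cohort(
    experiment: str,
    n_per_group: int = 8,
    params: LearnerParams = LearnerParams(),
    seed: int = 0,
    frame_jitter: float = 0.1,
    frame_rates=(60.0, 120.0, 144.0),
    camera_distance: float = 10.0,
    inverted_axes: str = "both",
    correction: bool = True,
    with_trajectories: bool = True,
) -> CohortData:
    """Simulate a full cohort for one experiment.

    Each group (context / trained context / probed context, depending on the
    experiment) gets ``n_per_group`` participants with rotation direction
    and input device counterbalanced within group. All randomness descends
    from ``seed`` through a spawned seed tree, so cohorts are reproducible
    and participants are independent.
    """
    if experiment not in GROUPS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ss = np.random.SeedSequence(seed)
    trial_parts, traj_parts = [], []
    pid = 0
    for group, kwargs in GROUPS[experiment]:
        for j in range(n_per_group):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            sched_seed = int(child.generate_state(1)[0] % 2**31)
            direction = "cw" if j % 2 == 0 else "ccw"
            device = "mouse" if (j // 2) % 2 == 0 else "trackpad"
            schedule = build_schedule(experiment, rotation_direction=direction, seed=sched_seed, **kwargs)
            learner_df = simulate_learner(
                params, schedule, seed=int(child.generate_state(2)[1] % 2**31),
                inverted_axes=inverted_axes,
            )
            frame_rate = float(frame_rates[pid % len(frame_rates)])
            trials, traj = _participant_trials(
                f"p{pid:03d}",
                experiment,
                schedule,
                learner_df,
                params,
                device,
                rng,
                frame_rate,
                frame_jitter,
                camera_distance,
                inverted_axes,
                correction,
                with_trajectories,
            )
            trials.insert(1, "group", group)
            trial_parts.append(trials)
            traj_parts.append(traj)
            pid += 1
    trials = pd.concat(trial_parts, ignore_index=True)
    trajectories = pd.concat(traj_parts, ignore_index=True)
    return CohortData(experiment=experiment, trials=trials, trajectories=trajectories)
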