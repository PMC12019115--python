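"""Experiment trial schedules and the adaptive time-limit staircase.

Four designs are supported, mirroring the study structure of a visuomotor
rotation experiment run in equated Point/Look contexts:

* ``exp1`` (680 trials): 100 baseline, 480 rotation, 100 washout, all in a
  single context, targets cycled over the four cardinal directions.
* ``exp2a`` / ``exp2b`` (800 trials): baseline in the untrained then trained
  context (100 each), 480 rotation trials in the trained context, then a
  100-trial transfer block in the untrained context and 20 final trials in
  the trained context. In ``exp2a`` the rotation is switched off for the
  last two blocks; in ``exp2b`` it stays on.
* ``exp3`` (760 trials): 60 two-context baseline trials to the vertical
  targets, 20 Point trials introducing the no-feedback return, a 15-cycle
  baseline generalization block (18 trials per cycle: 3 probes + 15 Point
  top-ups), 120 rotated Point trials to the top target, the generalization
  block proper, and 20 unperturbed Point after-effect trials.

The per-trial time limit (experiments 1 and 2) is controlled by a pair of
interleaved 1-up/1-down staircases stepping by 30 ms, which drives the hit
rate toward ~50%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import INVERTED_LOOK, LOOK, POINT

__all__ = [
    "Schedule",
    "StaircaseState",
    "build_schedule",
    "init_staircases",
    "staircase_limit",
    "update_staircase",
    "EXPERIMENTS",
    "TRIAL_COUNTS",
]

EXPERIMENTS = ("exp1", "exp2a", "exp2b", "exp3")
TRIAL_COUNTS = {"exp1": 680, "exp2a": 800, "exp2b": 800, "exp3": 760}

CARDINAL_TARGETS = np.array([0.0, 90.0, 180.0, 270.0])
ROTATION_MAGNITUDE = 30.0
STAIRCASE_STEP_MS = 30.0
STAIRCASE_INITS_MS = {"mouse": (450.0, 1050.0), "trackpad": (780.0, 1380.0)}

SCHEDULE_COLUMNS = [
    "schedule_index",
    "block_label",
    "cycle_index",
    "context",
    "target_angle",
    "rotation_deg",
    "probe_flag",
    "return_feedback",
    "online_check",
    "gen_cycle",
]


@dataclass(frozen=True)
class Schedule:
    """An ordered experiment plan: one row per scheduled trial."""

    experiment: str
    rotation_direction: str
    trials: pd.DataFrame

    def __len__(self):
        return len(self.trials)


def _signed_rotation(direction: str) -> float:
    if direction == "ccw":
        return ROTATION_MAGNITUDE
    if direction == "cw":
        return -ROTATION_MAGNITUDE
    raise ValueError(f"rotation direction must be 'cw' or 'ccw', got {direction!r}")


def _cycled_block(rng, n_cycles, block, context, rotation_deg, cycle_offset, online_check=False):
    rows = []
    for c in range(n_cycles):
        for target in rng.permutation(CARDINAL_TARGETS):
            rows.append(
                dict(
                    block_label=block,
                    cycle_index=cycle_offset + c + 1,
                    context=context,
                    target_angle=float(target),
                    rotation_deg=rotation_deg,
                    probe_flag=False,
                    return_feedback=True,
                    online_check=online_check,
                    gen_cycle=np.nan,
                )
            )
    return rows


def _build_exp1(rng, rot, context):
    rows = []
    blocks = [("baseline", 25, 0.0), ("rotation", 120, rot), ("washout", 25, 0.0)]
    offset = 0
    for label, n_cycles, r in blocks:
        rows += _cycled_block(rng, n_cycles, label, context, r, offset)
        offset += n_cycles
    return rows


def _build_exp2(rng, rot, trained_context, keep_rotation_on):
    untrained = LOOK if trained_context == POINT else POINT
    late_rot = rot if keep_rotation_on else 0.0
    blocks = [
        ("baseline_untrained", 25, untrained, 0.0),
        ("baseline_trained", 25, trained_context, 0.0),
        ("rotation", 120, trained_context, rot),
        ("transfer", 25, untrained, late_rot),
        ("final_trained", 5, trained_context, late_rot),
    ]
    rows = []
    offset = 0
    for label, n_cycles, context, r in blocks:
        rows += _cycled_block(rng, n_cycles, label, context, r, offset, online_check=True)
        offset += n_cycles
    return rows


def _exp3_row(block, context, target, rotation_deg, probe=False, return_feedback=True,
              online_check=True, gen_cycle=np.nan):
    return dict(
        block_label=block,
        cycle_index=np.nan,
        context=context,
        target_angle=float(target),
        rotation_deg=rotation_deg,
        probe_flag=probe,
        return_feedback=return_feedback,
        online_check=online_check,
        gen_cycle=gen_cycle,
    )


def _vertical_pairs(rng, n_trials):
    targets = []
    for _ in range(n_trials // 2):
        targets.extend(rng.permutation([90.0, 270.0]))
    return targets


def _exp3_generalization_block(rng, block, probe_context, topup_rotation):
    """15 cycles of 18 trials: probe to a lateral target, the two vertical
    targets (top first in 7 or 8 randomly chosen cycles), then 15 Point
    top-up trials to the top target."""
    n_cycles = 15
    n_top_first = int(rng.choice([7, 8]))
    top_first = np.zeros(n_cycles, dtype=bool)
    top_first[rng.choice(n_cycles, size=n_top_first, replace=False)] = True
    rows = []
    for c in range(n_cycles):
        lateral = float(rng.choice([0.0, 180.0]))
        vertical = [90.0, 270.0] if top_first[c] else [270.0, 90.0]
        for target in [lateral] + vertical:
            rows.append(
                _exp3_row(block, probe_context, target, 0.0, probe=True,
                          online_check=False, gen_cycle=c + 1)
            )
        for _ in range(15):
            rows.append(
                _exp3_row(
                    block, POINT, 90.0, topup_rotation,
                    return_feedback=False, gen_cycle=c + 1,
                )
            )
    return rows


def _build_exp3(rng, rot, probe_context):
    rows = []
    # 60 baseline trials to the vertical targets: two contiguous 20-trial
    # context runs in random order, then 20 trials with contexts interleaved.
    contexts = [POINT, probe_context]
    if rng.random() < 0.5:
        contexts = contexts[::-1]
    for ctx in contexts:
        for target in _vertical_pairs(rng, 20):
            rows.append(_exp3_row("baseline", ctx, target, 0.0))
    first = contexts[int(rng.random() < 0.5)]
    second = probe_context if first == POINT else POINT
    interleaved_targets = _vertical_pairs(rng, 20)
    for i, target in enumerate(interleaved_targets):
        rows.append(_exp3_row("baseline", first if i % 2 == 0 else second, target, 0.0))
    # 20 Point trials to the top target introducing the no-feedback return;
    # from here on Point trials never have return feedback.
    for _ in range(20):
        rows.append(_exp3_row("baseline_no_return", POINT, 90.0, 0.0, return_feedback=False))
    rows += _exp3_generalization_block(rng, "baseline_generalization", probe_context, 0.0)
    for _ in range(120):
        rows.append(_exp3_row("rotation", POINT, 90.0, rot, return_feedback=False))
    rows += _exp3_generalization_block(rng, "generalization", probe_context, rot)
    for _ in range(20):
        rows.append(_exp3_row("washout", POINT, 90.0, 0.0, return_feedback=False))
    return rows


def build_schedule(
    experiment: str,
    rotation_direction: str = "cw",
    seed: int = 0,
    context: str = POINT,
    trained_context: str = POINT,
    probe_context: str = LOOK,
) -> Schedule:
    """Build the ordered trial plan for one participant.

    ``context`` selects the group context for exp1, ``trained_context`` the
    trained context for exp2a/2b, and ``probe_context`` (``look`` or
    ``inverted_look``) the probed context for exp3.
    """
    rng = np.random.default_rng(seed)
    rot = _signed_rotation(rotation_direction)
    if experiment == "exp1":
        rows = _build_exp1(rng, rot, context)
    elif experiment in ("exp2a", "exp2b"):
        rows = _build_exp2(rng, rot, trained_context, keep_rotation_on=experiment == "exp2b")
    elif experiment == "exp3":
        if probe_context not in (LOOK, INVERTED_LOOK):
            raise ValueError(f"probe context must be look or inverted_look, got {probe_context!r}")
        rows = _build_exp3(rng, rot, probe_context)
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    trials = pd.DataFrame(rows)
    trials.insert(0, "schedule_index", np.arange(len(trials)))
    assert len(trials) == TRIAL_COUNTS[experiment]
    return Schedule(experiment=experiment, rotation_direction=rotation_direction, trials=trials)


# ---------------------------------------------------------------------------
# Time-limit staircases


@dataclass(frozen=True)
class StaircaseState:
    """Two interleaved 1-up/1-down staircases on the trial time limit."""

    limits: tuple
    step: float = STAIRCASE_STEP_MS
    next_index: int = 0
    usage_counts: tuple = (0, 0)

    def __post_init__(self):
        if len(self.limits) != 2 or any(v <= 0 for v in self.limits):
            raise ValueError("limits must be a positive pair")


def init_staircases(device: str) -> StaircaseState:
    """Initial staircase pair for a device (mouse: 450/1050 ms, trackpad:
    780/1380 ms), stepping by 30 ms."""
    try:
        limits = STAIRCASE_INITS_MS[device]
    except KeyError:
        raise ValueError(f"unknown device {device!r}") from None
    return StaircaseState(limits=limits)


def staircase_limit(state: StaircaseState) -> float:
    """Time limit (ms) for the upcoming trial."""
    return state.limits[state.next_index]


def update_staircase(state: StaircaseState, success: bool) -> StaircaseState:
    """Apply the trial outcome: the tested staircase's limit decreases by one
    step after a success and increases by one step after a failure (floored
    at one step, since a time limit must stay positive); usage alternates so
    both staircases are used equally."""
    i = state.next_index
    limits = list(state.limits)
    limits[i] = max(state.step, limits[i] + (-state.step if success else state.step))
    counts = list(state.usage_counts)
    counts[i] += 1
    return replace(
        state,
        limits=tuple(limits),
        usage_counts=tuple(counts),
        next_index=1 - i,
    )
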