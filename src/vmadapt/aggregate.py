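"""Cycle series, period means, after-effect/transfer, and generalization.

Trials in the cycled designs are grouped into cycles of four consecutive
movements (one per cardinal target) and averaged over valid trials; repeated
(online-aborted) trials replace their originals in sequence, so cycle
membership comes from the schedule. Periods are fixed windows on the cycle
(or, for the single-target design, trial) series:

* baseline — last 10 cycles of the (trained-context) baseline block,
* early/late rotation — first/last 10 cycles of the rotation block,
* early/late washout — first/last 10 cycles of the washout block,
* early transfer — first 10 cycles of the transfer block,
* early/late learning (single-target design) — first/last 10 *trials* of
  the rotation block.

Derived measures: after-effect = early washout − late rotation; transfer =
early transfer − late rotation; generalization probes are baseline-corrected
per participant and target and labelled by their relation to the trained
hand direction (the upward hand movement).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .learner import planned_hand_direction

__all__ = [
    "assign_cycles",
    "period_means",
    "after_effect",
    "transfer_measure",
    "baseline_correct",
    "topup_asymptote",
    "PERIOD_WINDOWS",
]

TRAINED_HAND_DIRECTION = 90.0

# period -> (block_label, which end, count, unit)
PERIOD_WINDOWS = {
    "exp1": {
        "baseline": ("baseline", "last", 10, "cycle"),
        "early_rotation": ("rotation", "first", 10, "cycle"),
        "late_rotation": ("rotation", "last", 10, "cycle"),
        "early_washout": ("washout", "first", 10, "cycle"),
        "late_washout": ("washout", "last", 10, "cycle"),
    },
    "exp2a": {
        "baseline": ("baseline_trained", "last", 10, "cycle"),
        "early_rotation": ("rotation", "first", 10, "cycle"),
        "late_rotation": ("rotation", "last", 10, "cycle"),
        "early_transfer": ("transfer", "first", 10, "cycle"),
    },
    "exp3": {
        "early_learning_trials": ("rotation", "first", 10, "trial"),
        "late_learning_trials": ("rotation", "last", 10, "trial"),
    },
}
PERIOD_WINDOWS["exp2b"] = PERIOD_WINDOWS["exp2a"]


def _merged(metrics: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    meta_cols = [
        c
        for c in (
            "block_label", "cycle_index", "context", "target_angle", "probe_flag",
            "gen_cycle", "schedule_index", "group", "rotation_direction", "outcome",
        )
        if c in trials.columns and c not in metrics.columns
    ]
    return metrics.merge(
        trials[["participant_id", "trial_index"] + meta_cols],
        on=["participant_id", "trial_index"],
        validate="one_to_one",
    )


def assign_cycles(metrics: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant cycle means over valid trials.

    Repeated trials inherit their original's cycle slot (in-place
    replacement), so the grouping key is the schedule's cycle index. Cycles
    with no valid trial yield a missing mean. Returns columns
    participant_id, block_label, cycle_index, mean_hand_angle, n_valid.
    """
    df = _merged(metrics, trials)
    df = df[np.isfinite(df["cycle_index"].astype(float))]
    valid = df[df["valid"]]
    grouped = valid.groupby(["participant_id", "block_label", "cycle_index"], sort=False)
    means = grouped["hand_angle"].mean().rename("mean_hand_angle")
    counts = grouped["hand_angle"].size().rename("n_valid")
    all_cycles = (
        df.groupby(["participant_id", "block_label", "cycle_index"], sort=False)
        .size()
        .rename("n_trials")
    )
    out = pd.concat([all_cycles, means, counts], axis=1).reset_index()
    out["n_valid"] = out["n_valid"].fillna(0).astype(int)
    out["cycle_index"] = out["cycle_index"].astype(int)
    return out.sort_values(["participant_id", "cycle_index"]).reset_index(drop=True)[
        ["participant_id", "block_label", "cycle_index", "mean_hand_angle", "n_valid"]
    ]


def _window(series: pd.DataFrame, order_col: str, end: str, count: int):
    ordered = series.sort_values(order_col)
    return ordered.head(count) if end == "first" else ordered.tail(count)


def period_means(
    cycles: pd.DataFrame,
    experiment: str,
    metrics: pd.DataFrame = None,
    trials: pd.DataFrame = None,
) -> pd.DataFrame:
    """Per-participant mean hand angle over each predefined period.

    ``cycles`` is the output of :func:`assign_cycles` (cycle-unit periods);
    trial-unit periods (the single-target design) additionally need the
    metrics and trial tables. Missing cycles are skipped; a window with no
    data at all yields NaN.
    """
    windows = PERIOD_WINDOWS[experiment]
    rows = []
    trial_df = None
    if any(unit == "trial" for _, _, _, unit in windows.values()):
        if metrics is None or trials is None:
            raise ValueError("trial-unit periods need metrics and trials tables")
        trial_df = _merged(metrics, trials)
    participants = (
        cycles["participant_id"].unique() if len(cycles) else trial_df["participant_id"].unique()
    )
    for pid in participants:
        row = {"participant_id": pid}
        for period, (block, end, count, unit) in windows.items():
            if unit == "cycle":
                sub = cycles[(cycles["participant_id"] == pid) & (cycles["block_label"] == block)]
                win = _window(sub, "cycle_index", end, count)
                vals = win["mean_hand_angle"].dropna()
            else:
                sub = trial_df[
                    (trial_df["participant_id"] == pid)
                    & (trial_df["block_label"] == block)
                    & trial_df["valid"]
                ]
                win = _window(sub, "schedule_index", end, count)
                vals = win["hand_angle"].dropna()
            row[period] = float(vals.mean()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def after_effect(periods: pd.DataFrame) -> pd.Series:
    """Early washout minus late rotation, per participant (negative when
    adaptation decays once the perturbation is removed)."""
    return periods["early_washout"] - periods["late_rotation"]


def transfer_measure(periods: pd.DataFrame) -> pd.Series:
    """Early transfer minus late rotation, per participant (0 = perfect
    carry-over of adaptation into the untrained context)."""
    return periods["early_transfer"] - periods["late_rotation"]


def _handspace_relation(target_angle: float, context: str, inverted_axes: str = "both") -> str:
    hand = planned_hand_direction(target_angle, context, inverted_axes)
    if hand == TRAINED_HAND_DIRECTION:
        return "trained"
    if hand == (TRAINED_HAND_DIRECTION + 180.0) % 360.0:
        return "untrained"
    return "lateral"


def baseline_correct(
    metrics: pd.DataFrame,
    trials: pd.DataFrame,
    gen_block: str = "generalization",
    baseline_block: str = "baseline_generalization",
    inverted_axes: str = "both",
) -> pd.DataFrame:
    """Baseline-corrected generalization probes.

    For each participant, probe context and probe target, the mean hand
    angle in the baseline generalization block is subtracted from the mean
    in the generalization block (removing intrinsic per-target biases).
    Targets are labelled by the relation of their planned hand direction to
    the trained (upward) hand direction: trained / untrained / lateral.
    """
    df = _merged(metrics, trials)
    probes = df[df["probe_flag"] & df["valid"]]

    def block_means(block):
        sub = probes[probes["block_label"] == block]
        return sub.groupby(["participant_id", "context", "target_angle"])["hand_angle"].mean()

    gen = block_means(gen_block)
    base = block_means(baseline_block)
    if not gen.index.equals(base.index):
        missing = gen.index.symmetric_difference(base.index)
        if len(missing):
            raise ValueError(f"unmatched probe target/context pairs: {list(missing)[:4]}")
    corrected = (gen - base).rename("corrected_hand_angle").reset_index()
    corrected["handspace_relation"] = [
        _handspace_relation(t, c, inverted_axes)
        for t, c in zip(corrected["target_angle"], corrected["context"])
    ]
    return corrected.rename(columns={"context": "probe_context", "target_angle": "probe_target"})


def topup_asymptote(metrics: pd.DataFrame, trials: pd.DataFrame, n_last: int = 5) -> pd.DataFrame:
    """Mean hand angle over the last ``n_last`` top-up trials of each
    generalization cycle — the re-asymptote check reported alongside the
    probes."""
    df = _merged(metrics, trials)
    topups = df[
        (df["block_label"] == "generalization") & ~df["probe_flag"] & df["valid"]
    ]
    rows = []
    for (pid, cyc), g in topups.groupby(["participant_id", "gen_cycle"]):
        tail = g.sort_values("schedule_index").tail(n_last)
        rows.append(
            {
                "participant_id": pid,
                "gen_cycle": int(cyc),
                "mean_hand_angle": float(tail["hand_angle"].mean()),
            }
        )
    return pd.DataFrame(rows)
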