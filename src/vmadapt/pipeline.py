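"""End-to-end orchestration: simulate -> preprocess -> extract -> analyze.

Every run is a pure function of (configuration, seed): outputs are stamped
with the configuration hash and master seed, per-stage exclusion counts are
logged, and rerunning with the same configuration reproduces the tables
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, kinematics, preprocess, simulate, stats
from .io import config_hash, default_config, read_trajectories, read_trials, write_trials, write_trajectories
from .learner import LearnerParams

__all__ = ["run_pipeline", "simulate_stage", "preprocess_stage", "extract_stage", "analyze_cohort"]


class PipelineError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage


def _learner_params(config) -> LearnerParams:
    return LearnerParams(**config["learner"])


def simulate_stage(config: dict) -> simulate.CohortData:
    sim = config["simulation"]
    geom = config["geometry"]
    return simulate.generate_cohort(
        config["experiment"],
        n_per_group=config["n_per_group"],
        params=_learner_params(config),
        seed=config["seed"],
        frame_jitter=sim["frame_jitter"],
        frame_rates=tuple(sim["frame_rates"]),
        camera_distance=geom["camera_distance"],
        inverted_axes=geom["inverted_axes"],
        correction=sim["correction"],
    )


def preprocess_stage(trajectories: pd.DataFrame, config: dict):
    cfg = preprocess.PreprocessConfig(**config["preprocessing"])
    return preprocess.preprocess_trials(trajectories, cfg)


def extract_stage(clean, trials, exclusions) -> pd.DataFrame:
    return kinematics.extract_metrics(clean, trials, exclusions)


def _result_to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (list, tuple)):
        return [_result_to_dict(o) for o in obj]
    return obj


def _anova_block(period_df, periods, trials):
    """Long-format early/late rotation table and its 2x2 mixed ANOVA."""
    groups = trials.groupby("participant_id")["group"].first()
    long = period_df.melt(
        id_vars="participant_id",
        value_vars=periods,
        var_name="period",
        value_name="value",
    )
    long["group"] = long["participant_id"].map(groups)
    anova = stats.mixed_anova(long, dv="value", within="period", between="group")
    contrasts = {
        at: stats.emm_contrast(long, at, dv="value", within="period", between="group")
        for at in periods
    }
    return long, anova, contrasts


def _group_values(series: pd.Series, trials: pd.DataFrame):
    groups = trials.groupby("participant_id")["group"].first()
    by_group = {}
    for pid, value in series.items():
        by_group.setdefault(groups[pid], []).append(value)
    return {g: np.asarray(v) for g, v in sorted(by_group.items())}


def _transfer_regressions(cycles, period_df, trials, first_cycle=170, last_cycle=195):
    """Random-intercept regression of hand angle on cycle across the
    transfer window, per trained group; the intercept (at the first
    transfer cycle) is tested against the group's asymptotic learning."""
    groups = trials.groupby("participant_id")["group"].first()
    asymptote = period_df.set_index("participant_id")["late_rotation"]
    results = {}
    window = cycles[
        cycles["cycle_index"].between(first_cycle, last_cycle)
        & cycles["mean_hand_angle"].notna()
    ].copy()
    window["group"] = window["participant_id"].map(groups)
    window["cycle"] = window["cycle_index"] - (first_cycle + 1)
    for group, sub in window.groupby("group"):
        ref = float(asymptote[groups[groups == group].index].mean())
        results[group] = stats.mixed_lm(
            sub, x="cycle", y="mean_hand_angle", intercept_ref=ref
        )
    return results


def _generalization_regressions(metrics, trials):
    """Per-cycle baseline-corrected trained-direction probe angles regressed
    on generalization cycle, per probed group."""
    df = aggregate._merged(metrics, trials)
    probes = df[df["probe_flag"] & df["valid"]].copy()
    probes["hand_dir_trained"] = [
        aggregate._handspace_relation(t, c) == "trained"
        for t, c in zip(probes["target_angle"], probes["context"])
    ]
    trained = probes[probes["hand_dir_trained"]]
    base = (
        trained[trained["block_label"] == "baseline_generalization"]
        .groupby("participant_id")["hand_angle"]
        .mean()
    )
    gen = trained[trained["block_label"] == "generalization"].copy()
    gen["corrected"] = gen["hand_angle"] - gen["participant_id"].map(base)
    gen["cycle"] = gen["gen_cycle"] - 1.0
    groups = trials.groupby("participant_id")["group"].first()
    gen["group"] = gen["participant_id"].map(groups)
    results = {}
    for group, sub in gen.groupby("group"):
        results[group] = stats.mixed_lm(sub, x="cycle", y="corrected")
    return results


def analyze_cohort(metrics: pd.DataFrame, trials: pd.DataFrame, experiment: str) -> dict:
    """Experiment-appropriate aggregate measures and statistics.

    Returns a dict with the period table, the learning ANOVA with
    marginal-mean contrasts, and the experiment's headline measures
    (after-effect, transfer, or baseline-corrected generalization).
    """
    out = {"experiment": experiment}
    if experiment in ("exp1", "exp2a", "exp2b"):
        cycles = aggregate.assign_cycles(metrics, trials)
        period_df = aggregate.period_means(cycles, experiment)
        out["periods"] = period_df
        out["cycles"] = cycles
        _, anova, contrasts = _anova_block(
            period_df, ["early_rotation", "late_rotation"], trials
        )
        out["learning_anova"] = anova
        out["learning_contrasts"] = contrasts
        if experiment == "exp1":
            measure = aggregate.after_effect(period_df.set_index("participant_id"))
            out["after_effect"] = measure
            label = "after_effect"
        else:
            measure = aggregate.transfer_measure(period_df.set_index("participant_id"))
            out["transfer"] = measure
            label = "transfer"
        by_group = _group_values(measure.dropna(), trials)
        if len(by_group) == 2:
            (ga, va), (gb, vb) = by_group.items()
            out[f"{label}_group_test"] = stats.t_tests(va, vb, paired=False)
        out[f"{label}_mean"] = float(measure.mean())
        if experiment in ("exp2a", "exp2b"):
            out["transfer_regression"] = _transfer_regressions(cycles, period_df, trials)
    elif experiment == "exp3":
        period_df = aggregate.period_means(
            pd.DataFrame(columns=["participant_id", "block_label", "cycle_index", "mean_hand_angle", "n_valid"]),
            experiment,
            metrics=metrics,
            trials=trials,
        )
        out["periods"] = period_df
        gen = aggregate.baseline_correct(metrics, trials)
        out["generalization"] = gen
        vertical = gen[gen["handspace_relation"].isin(["trained", "untrained"])]
        groups = trials.groupby("participant_id")["group"].first()
        vertical = vertical.assign(group=vertical["participant_id"].map(groups))
        wide = vertical.pivot_table(
            index=["participant_id", "group"],
            columns="handspace_relation",
            values="corrected_hand_angle",
        ).reset_index()
        long = wide.melt(
            id_vars=["participant_id", "group"],
            value_vars=["trained", "untrained"],
            var_name="period",
            value_name="value",
        )
        out["generalization_anova"] = stats.mixed_anova(
            long, dv="value", within="period", between="group"
        )
        paired = {}
        for group, g in wide.groupby("group"):
            paired[group] = stats.t_tests(
                g["trained"].to_numpy(), g["untrained"].to_numpy(), paired=True
            )
        out["trained_vs_untrained"] = paired
        diff = (wide["trained"] - wide["untrained"]).groupby(wide["group"]).apply(list)
        if len(diff) == 2:
            out["generalization_group_test"] = stats.t_tests(
                np.asarray(diff.iloc[0]), np.asarray(diff.iloc[1]), paired=False
            )
        out["trained_generalization_regression"] = _generalization_regressions(metrics, trials)
        out["topup_asymptote"] = aggregate.topup_asymptote(metrics, trials)
        out["topup_mean"] = (
            float(out["topup_asymptote"]["mean_hand_angle"].mean())
            if len(out["topup_asymptote"])
            else float("nan")
        )
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return out


def _exclusion_summary(trials, exclusions, metrics):
    n = len(trials)
    reasons = exclusions["reason"].value_counts().to_dict() if len(exclusions) else {}
    return {
        "trials_recorded": int(n),
        "repeated_trials": int(trials["outcome"].eq("jump_start_repeat").sum()),
        "excluded_preprocessing": {k: int(v) for k, v in reasons.items()},
        "excluded_jump_start": int(metrics["jump_start"].sum()),
        "valid_trials": int(metrics["valid"].sum()),
    }


def run_pipeline(config: dict = None, output_dir=None) -> dict:
    """Run the full pipeline and write all outputs.

    Writes trials.csv, trajectories.csv, metrics.csv, cycles/periods tables,
    exclusions.csv, results.json and meta.json (configuration hash + seed)
    into the configured output directory, and returns the in-memory bundle.
    """
    from .io import _deep_update

    config = _deep_update(default_config(), config or {})
    outdir = Path(output_dir or config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        cohort = simulate_stage(config)
    except Exception as err:  # pragma: no cover - error path
        raise PipelineError("simulate", err) from err
    try:
        clean, exclusions = preprocess_stage(cohort.trajectories, config)
    except Exception as err:  # pragma: no cover
        raise PipelineError("preprocess", err) from err
    try:
        metrics = extract_stage(clean, cohort.trials, exclusions)
    except Exception as err:  # pragma: no cover
        raise PipelineError("extract", err) from err
    try:
        results = analyze_cohort(metrics, cohort.trials, config["experiment"])
    except Exception as err:
        raise PipelineError("analyze", err) from err

    meta = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "exclusions": _exclusion_summary(cohort.trials, exclusions, metrics),
    }
    write_trials(cohort.trials, outdir / "trials.csv")
    write_trajectories(cohort.trajectories, outdir / "trajectories.csv")
    metrics.to_csv(outdir / "metrics.csv", index=False)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    serializable = {}
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(outdir / f"{key}.csv", index=False)
            serializable[key] = f"{key}.csv"
        elif isinstance(value, pd.Series):
            serializable[key] = {str(k): float(v) for k, v in value.items()}
        elif isinstance(value, dict):
            serializable[key] = {k: _result_to_dict(v) for k, v in value.items()}
        else:
            serializable[key] = _result_to_dict(value)
    with open(outdir / "results.json", "w") as fh:
        json.dump({"meta": meta, "results": serializable}, fh, indent=2, default=str)
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return {
        "config": config,
        "trials": cohort.trials,
        "trajectories": cohort.trajectories,
        "metrics": metrics,
        "exclusions": exclusions,
        "results": results,
        "meta": meta,
    }
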