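import numpy as np
import pandas as pd
import pytest

from vmadapt import aggregate as A


def make_tables(angles, valid=None, block="rotation", cycle_start=1,
                context="point", outcome="hit"):
    """Minimal metrics/trials tables for one participant."""
    n = len(angles)
    valid = [True] * n if valid is None else valid
    trials = pd.DataFrame(
        {
            "participant_id": "p0",
            "trial_index": np.arange(n),
            "schedule_index": np.arange(n),
            "block_label": block,
            "cycle_index": cycle_start + np.arange(n) // 4,
            "context": context,
            "target_angle": np.tile([0.0, 90.0, 180.0, 270.0], n // 4 + 1)[:n],
            "probe_flag": False,
            "gen_cycle": np.nan,
            "group": "point",
            "rotation_direction": "cw",
            "outcome": outcome,
        }
    )
    metrics = pd.DataFrame(
        {
            "participant_id": "p0",
            "trial_index": np.arange(n),
            "hand_angle": angles,
            "valid": valid,
        }
    )
    return metrics, trials


class TestAssignCycles:
    def test_simple_means(self):
        metrics, trials = make_tables(np.arange(1.0, 9.0))
        out = A.assign_cycles(metrics, trials)
        assert list(out["mean_hand_angle"]) == [2.5, 6.5]
        assert list(out["n_valid"]) == [4, 4]

    def test_invalid_trials_excluded(self):
        metrics, trials = make_tables([10.0, 10.0, 10.0, 999.0], valid=[True, True, True, False])
        out = A.assign_cycles(metrics, trials)
        assert out.loc[0, "mean_hand_angle"] == 10.0
        assert out.loc[0, "n_valid"] == 3

    def test_all_invalid_cycle_missing(self):
        metrics, trials = make_tables([1.0, 2.0, 3.0, 4.0], valid=[False] * 4)
        out = A.assign_cycles(metrics, trials)
        assert np.isnan(out.loc[0, "mean_hand_angle"])
        assert out.loc[0, "n_valid"] == 0

    def test_permutation_invariance(self, rng):
        angles = rng.normal(0, 5, 8)
        metrics, trials = make_tables(angles)
        base = A.assign_cycles(metrics, trials)["mean_hand_angle"]
        perm = np.concatenate([rng.permutation(4), 4 + rng.permutation(4)])
        shuffled = A.assign_cycles(
            metrics.assign(hand_angle=angles[perm]), trials
        )["mean_hand_angle"]
        assert np.allclose(base, shuffled)


class TestPeriodMeans:
    def test_constant_series(self):
        cycles = pd.DataFrame(
            {
                "participant_id": "p0",
                "block_label": (["baseline"] * 25 + ["rotation"] * 120 + ["washout"] * 25),
                "cycle_index": np.arange(1, 171),
                "mean_hand_angle": 20.0,
                "n_valid": 4,
            }
        )
        out = A.period_means(cycles, "exp1")
        for period in A.PERIOD_WINDOWS["exp1"]:
            assert out.loc[0, period] == 20.0

    def test_first_last_windows(self):
        cycles = pd.DataFrame(
            {
                "participant_id": "p0",
                "block_label": "rotation",
                "cycle_index": np.arange(1, 121),
                "mean_hand_angle": np.arange(1.0, 121.0),
                "n_valid": 4,
            }
        )
        out = A.period_means(cycles, "exp1")
        assert out.loc[0, "early_rotation"] == 5.5
        assert out.loc[0, "late_rotation"] == 115.5

    def test_exp3_uses_trials_not_cycles(self):
        angles = np.arange(120.0)
        metrics, trials = make_tables(angles, block="rotation")
        out = A.period_means(pd.DataFrame(), "exp3", metrics=metrics, trials=trials)
        assert out.loc[0, "early_learning_trials"] == np.mean(angles[:10])
        assert out.loc[0, "late_learning_trials"] == np.mean(angles[-10:])


class TestDerivedMeasures:
    def test_after_effect_arithmetic(self):
        periods = pd.DataFrame({"early_washout": [15.0, 20.0], "late_rotation": [20.0, 20.0]})
        assert list(A.after_effect(periods)) == [-5.0, 0.0]

    def test_transfer_arithmetic(self):
        periods = pd.DataFrame({"early_transfer": [21.0, 22.0], "late_rotation": [22.0, 22.0]})
        assert list(A.transfer_measure(periods)) == [-1.0, 0.0]

    def test_linearity(self, rng):
        p = pd.DataFrame(
            {
                "early_washout": rng.normal(size=10),
                "early_transfer": rng.normal(size=10),
                "late_rotation": rng.normal(size=10),
            }
        )
        shifted = p + 3.0
        assert np.allclose(A.after_effect(p), A.after_effect(shifted))
        assert np.allclose(A.transfer_measure(p), A.transfer_measure(shifted))


def make_probe_tables(gen_values, base_values, context="look"):
    rows_m, rows_t = [], []
    idx = 0
    for block, values in [("baseline_generalization", base_values), ("generalization", gen_values)]:
        for target, val in values.items():
            rows_t.append(
                dict(
                    participant_id="p0", trial_index=idx, schedule_index=idx,
                    block_label=block, cycle_index=np.nan, context=context,
                    target_angle=target, probe_flag=True, gen_cycle=1,
                    group="g", rotation_direction="cw", outcome="hit",
                )
            )
            rows_m.append(
                dict(participant_id="p0", trial_index=idx, hand_angle=val, valid=True)
            )
            idx += 1
    return pd.DataFrame(rows_m), pd.DataFrame(rows_t)


class TestBaselineCorrect:
    def test_identical_blocks_zero(self):
        values = {0.0: 1.0, 90.0: 2.0, 180.0: 3.0, 270.0: 4.0}
        metrics, trials = make_probe_tables(values, values)
        out = A.baseline_correct(metrics, trials)
        assert np.allclose(out["corrected_hand_angle"], 0.0)

    def test_subtraction(self):
        metrics, trials = make_probe_tables({90.0: 12.0}, {90.0: 2.0})
        out = A.baseline_correct(metrics, trials)
        assert out.loc[0, "corrected_hand_angle"] == 10.0
        assert out.loc[0, "handspace_relation"] == "trained"

    def test_inverted_look_relations(self):
        values = {0.0: 0.0, 90.0: 0.0, 180.0: 0.0, 270.0: 0.0}
        metrics, trials = make_probe_tables(values, values, context="inverted_look")
        out = A.baseline_correct(metrics, trials).set_index("probe_target")
        # the top screen target needs a downward hand movement: untrained
        assert out.loc[90.0, "handspace_relation"] == "untrained"
        assert out.loc[270.0, "handspace_relation"] == "trained"
        assert out.loc[0.0, "handspace_relation"] == "lateral"
        assert out.loc[180.0, "handspace_relation"] == "lateral"

    def test_unmatched_pairs_rejected(self):
        metrics, trials = make_probe_tables({90.0: 1.0, 270.0: 2.0}, {90.0: 1.0})
        with pytest.raises(ValueError):
            A.baseline_correct(metrics, trials)
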