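import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vmadapt import stats as V


def mixed_design_frame(group_a, group_b, within_labels=("early", "late")):
    """Long frame from per-group (n_subjects x n_within) value arrays."""
    rows = []
    for gi, (label, values) in enumerate([("a", group_a), ("b", group_b)]):
        for si, subject_values in enumerate(np.atleast_2d(values)):
            for w, v in zip(within_labels, subject_values):
                rows.append(
                    dict(participant_id=f"{label}{si}", group=label, period=w, value=v)
                )
    return pd.DataFrame(rows)


def brute_force_mixed_anova(group_a, group_b):
    """Direct sums-of-squares for a balanced 2 x w mixed design."""
    a, b = np.atleast_2d(group_a), np.atleast_2d(group_b)
    data = np.stack([a, b])  # (2, n, w)
    g, n, w = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=2)
    group_means = data.mean(axis=(1, 2))
    w_means = data.mean(axis=(0, 1))
    cell_means = data.mean(axis=1)
    ss_between_subj = w * ((subj_means - grand) ** 2).sum()
    ss_group = n * w * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_total = ((data - grand) ** 2).sum()
    ss_within = ss_total - ss_between_subj
    ss_w = g * n * ((w_means - grand) ** 2).sum()
    ss_gw = n * ((cell_means - group_means[:, None] - w_means[None, :] + grand) ** 2).sum()
    ss_err = ss_within - ss_w - ss_gw
    df_group, df_subj = g - 1, g * (n - 1)
    df_w, df_gw, df_err = w - 1, (g - 1) * (w - 1), g * (n - 1) * (w - 1)
    return {
        "group": (ss_group / df_group) / (ss_subj_within / df_subj),
        "period": (ss_w / df_w) / (ss_err / df_err),
        "group x period": (ss_gw / df_gw) / (ss_err / df_err),
    }


class TestMixedAnova:
    def test_identical_groups_zero_f(self):
        values = np.tile([3.0, 3.0], (4, 1))
        res = V.mixed_anova(mixed_design_frame(values, values))
        assert all(r.F == 0.0 for r in res)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(3, 8)
            a = rng.normal(0, 1, (n, 2))
            b = rng.normal(0.5, 1, (n, 2))
            res = {r.effect: r for r in V.mixed_anova(mixed_design_frame(a, b))}
            oracle = brute_force_mixed_anova(a, b)
            for effect, F in oracle.items():
                assert abs(res[effect].F - F) < 1e-8

    def test_pure_within_effect(self):
        base = np.tile([1.0, 11.0], (5, 1))
        res = {r.effect: r for r in V.mixed_anova(mixed_design_frame(base, base))}
        assert res["group x period"].F == pytest.approx(0.0, abs=1e-12)
        assert res["period"].F > 1e6 or np.isinf(res["period"].F)

    def test_single_within_level_equals_t_squared(self, rng):
        a = rng.normal(0, 1, (6, 1))
        b = rng.normal(1, 1, (6, 1))
        res = V.mixed_anova(mixed_design_frame(a, b, within_labels=("only",)))
        t = sps.ttest_ind(a.ravel(), b.ravel(), equal_var=True).statistic
        assert len(res) == 1
        assert res[0].F == pytest.approx(t**2, rel=1e-10)

    def test_eta_p2_identity(self, rng):
        a = rng.normal(0, 1, (5, 2))
        b = rng.normal(1, 1, (5, 2))
        for r in V.mixed_anova(mixed_design_frame(a, b)):
            assert r.eta_p2 == pytest.approx(
                r.F * r.df_num / (r.F * r.df_num + r.df_den), rel=1e-10
            )

    def test_unbalanced_within_rejected(self):
        df = mixed_design_frame(np.ones((3, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError):
            V.mixed_anova(df.iloc[:-1])


class TestEmmContrast:
    def test_zero_difference(self):
        values = np.tile([2.0, 4.0], (4, 1))
        res = V.emm_contrast(mixed_design_frame(values, values), at="early")
        assert res.estimate == 0.0 and abs(res.t) < 1e-12

    def test_known_offset_matches_pooled_t(self, rng):
        a = rng.normal(0, 1, (6, 2))
        b = a + 2.0
        res = V.emm_contrast(mixed_design_frame(a, b), at="late")
        t = sps.ttest_ind(a[:, 1], b[:, 1], equal_var=True)
        assert res.estimate == pytest.approx(-2.0)
        assert res.t == pytest.approx(t.statistic, rel=1e-12)
        assert res.df == 10

    def test_ci_p_duality(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, (5, 2))
            b = rng.normal(0.8, 1, (5, 2))
            res = V.emm_contrast(mixed_design_frame(a, b), at="early")
            excludes_zero = res.ci_low > 0 or res.ci_high < 0
            assert excludes_zero == (res.p < 0.05)

    def test_unknown_level(self):
        with pytest.raises(ValueError):
            V.emm_contrast(mixed_design_frame(np.ones((3, 2)), np.ones((3, 2))), at="nope")


class TestTTests:
    def test_welch_example(self):
        res = V.t_tests([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert res.estimate == -1.0
        assert res.t == pytest.approx(-1.224744871, rel=1e-8)

    def test_paired_identical(self):
        res = V.t_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.degenerate and res.estimate == 0.0 and res.t == 0.0 and res.p == 1.0

    def test_paired_constant_shift_degenerate(self):
        res = V.t_tests([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], paired=True)
        assert res.degenerate and res.estimate == -1.0

    def test_paired_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        res = V.t_tests(a, b, paired=True)
        ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            V.t_tests([1.0], [2.0])


class TestBayesFactor:
    def test_identical_models(self):
        assert V.bf10_approx(-10.0, -10.0, 20, 2, 2) == pytest.approx(1.0)

    def test_delta_bic_2ln3(self):
        # log-likelihood advantage of ln(3) for H1 at equal complexity
        assert V.bf10_approx(-10.0, -10.0 + np.log(3), 20, 2, 2) == pytest.approx(3.0)

    def test_parameter_guard(self):
        with pytest.raises(ValueError):
            V.bf10_approx(0.0, 0.0, 2, 2, 2)


class TestMixedLM:
    def test_noiseless_line_exact(self):
        rows = [
            dict(participant_id=i, cycle=c, value=2 + 0.5 * c)
            for i in range(3)
            for c in range(6)
        ]
        with pytest.warns(UserWarning):
            res = V.mixed_lm(pd.DataFrame(rows))
        slope = next(r for r in res if r.term == "cycle")
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert not slope.satterthwaite  # fixed-effects fallback path

    def test_single_participant_falls_back(self):
        rows = [dict(participant_id=0, cycle=c, value=c + 0.1) for c in range(5)]
        res = V.mixed_lm(pd.DataFrame(rows))
        assert all(not r.satterthwaite for r in res)

    def test_intercept_reference_offset(self, rng):
        rows = [
            dict(participant_id=i, cycle=c, value=5.0 + rng.normal(0, 0.1) + 0.05 * rng.normal())
            for i in range(10)
            for c in range(8)
        ]
        df = pd.DataFrame(rows)
        near = V.mixed_lm(df, intercept_ref=5.0)
        far = V.mixed_lm(df, intercept_ref=0.0)
        t_near = next(r for r in near if r.term == "intercept").t
        t_far = next(r for r in far if r.term == "intercept").t
        assert abs(t_near) < abs(t_far)

    def test_satterthwaite_df_scales(self, rng):
        """Intercept df tracks the number of participants (between
        information), while the slope df tracks the observation count."""
        rows = [
            dict(participant_id=i, cycle=c,
                 value=1.0 + 0.1 * c + rng.normal(0, 3) * 0 + rng.normal(0, 1))
            for i in range(20)
            for c in range(10)
        ]
        # add genuine participant offsets
        df = pd.DataFrame(rows)
        offsets = {i: v for i, v in enumerate(rng.normal(0, 3, 20))}
        df["value"] += df["participant_id"].map(offsets)
        res = {r.term: r for r in V.mixed_lm(df)}
        assert res["intercept"].satterthwaite
        assert res["intercept"].df < 40
        assert res["cycle"].df > 100

    def test_slope_ci_coverage(self, rng):
        """The slope's 95% CI covers the generating slope at close to the
        nominal rate across simulated random-intercept datasets."""
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            rows = []
            for i in range(30):
                u = rng.normal(0, 3)
                x = np.arange(26)
                y = 2.0 + 0.1 * x + u + rng.normal(0, 1, 26)
                rows.append(pd.DataFrame(dict(participant_id=i, cycle=x, value=y)))
            res = V.mixed_lm(pd.concat(rows))
            slope = next(r for r in res if r.term == "cycle")
            hits += slope.ci_low <= 0.1 <= slope.ci_high
        assert hits / n_sims >= 0.93
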