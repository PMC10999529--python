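"""Survival estimation and group tests against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from alsonset import (
    group_summary,
    kaplan_meier,
    logrank,
    logrank_trend,
    mann_whitney,
    shapiro_wilk,
    tukey_hsd,
    two_way_anova,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def logrank_chi2_oracle(times, events, grp):
    """Textbook Mantel-Cox chi-square, computed from first principles."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    grp = np.asarray(grp, int)
    o_minus_e = 0.0
    var = 0.0
    for tj in np.unique(times[events == 1]):
        at_risk = times >= tj
        n_j = at_risk.sum()
        d_j = ((times == tj) & (events == 1)).sum()
        n1 = (at_risk & (grp == 1)).sum()
        d1 = ((times == tj) & (events == 1) & (grp == 1)).sum()
        o_minus_e += d1 - d_j * n1 / n_j
        if n_j > 1:
            var += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def logrank_permutation_p(times, events, n_a):
    """Exact permutation p-value of the log-rank chi-square."""
    n = len(times)
    grp0 = np.zeros(n, int)
    grp0[:n_a] = 1
    observed = logrank_chi2_oracle(times, events, grp0)
    count = total = 0
    for comb in itertools.combinations(range(n), n_a):
        g = np.zeros(n, int)
        g[list(comb)] = 1
        if logrank_chi2_oracle(times, events, g) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def mw_exact_p_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration (no ties)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(sample_a, sample_b):
        return sum(x > y for x in sample_a for y in sample_b)

    observed = u_stat(a, b)
    mu = n_a * len(b) / 2
    dev = abs(observed - mu)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if abs(u_stat(sa, sb) - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def balanced_anova_oracle(values, genotype, activity):
    """Closed-form sums of squares for a balanced two-factor design."""
    values = np.asarray(values, float)
    genotype = np.asarray(genotype)
    activity = np.asarray(activity)
    grand = values.mean()
    levels_g = np.unique(genotype)
    levels_a = np.unique(activity)
    r = len(values) / (len(levels_g) * len(levels_a))
    ss_g = sum(
        (values[genotype == g].mean() - grand) ** 2 * (genotype == g).sum()
        for g in levels_g
    )
    ss_a = sum(
        (values[activity == a].mean() - grand) ** 2 * (activity == a).sum()
        for a in levels_a
    )
    ss_int = 0.0
    ss_err = 0.0
    for g in levels_g:
        for a in levels_a:
            cell = values[(genotype == g) & (activity == a)]
            ss_int += r * (
                cell.mean()
                - values[genotype == g].mean()
                - values[activity == a].mean()
                + grand
            ) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    df_g, df_a = len(levels_g) - 1, len(levels_a) - 1
    df_int = df_g * df_a
    df_err = len(values) - len(levels_g) * len(levels_a)
    mse = ss_err / df_err
    return {
        "genotype": (ss_g, ss_g / df_g / mse),
        "activity": (ss_a, ss_a / df_a / mse),
        "interaction": (ss_int, ss_int / df_int / mse),
    }


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        curve = kaplan_meier([10, 20, 30], [0, 0, 0])
        assert all(s == 1.0 for s in curve.survival)

    def test_hand_product_limit_with_censoring(self):
        # n=2: event at 10, censored at 20 -> S(10) = 1/2
        curve = kaplan_meier([10, 20], [1, 0])
        assert curve.survival[curve.times.index(10.0)] == pytest.approx(0.5)

    def test_hand_product_limit_all_events(self):
        curve = kaplan_meier([10, 20], [1, 1])
        assert curve.survival[curve.times.index(10.0)] == pytest.approx(0.5)
        assert curve.survival[curve.times.index(20.0)] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 50, size=30).astype(float)
        curve = kaplan_meier(times, np.ones_like(times, int))
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean())

    def test_at_risk_accounting(self):
        curve = kaplan_meier([5, 5, 8, 12], [1, 0, 1, 1])
        assert curve.at_risk[curve.times.index(5.0)] == 4
        assert curve.at_risk[curve.times.index(8.0)] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

# small instances with varied censoring; permutation p known to be well
# approximated by the 1-df chi-square at these configurations
LOGRANK_INSTANCES = [
    ([9, 15, 20, 25, 26, 27, 29], [1, 1, 1, 1, 1, 1, 1],
     [6, 8, 15, 15, 27, 28, 29], [1, 1, 0, 1, 1, 1, 1]),
    ([8, 17, 19, 21, 26, 29], [1, 1, 1, 0, 1, 0],
     [8, 8, 10, 13, 20, 28], [0, 1, 0, 1, 0, 1]),
    ([5, 6, 9, 19, 21, 22, 22, 28], [1, 1, 1, 1, 1, 1, 1, 1],
     [4, 5, 5, 11, 12, 15, 21, 22], [1, 1, 0, 1, 1, 0, 0, 1]),
]


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [10, 20, 30, 40]
        e = [1, 1, 0, 1]
        res = logrank(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_significant_at_study_size(self):
        # all trained onsets strictly before all sedentary onsets, n=12/group
        a = list(range(50, 62))
        b = list(range(70, 82))
        res = logrank(a, [1] * 12, b, [1] * 12)
        assert res.p_value < 0.05

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank([5, 6], [0, 0], [7, 8], [0, 0])

    @pytest.mark.parametrize("ta,ea,tb,eb", LOGRANK_INSTANCES)
    def test_statistic_matches_first_principles_oracle(self, ta, ea, tb, eb):
        res = logrank(ta, ea, tb, eb)
        grp = np.r_[np.ones(len(ta), int), np.zeros(len(tb), int)]
        oracle = logrank_chi2_oracle(ta + tb, ea + eb, grp)
        assert res.statistic == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("ta,ea,tb,eb", LOGRANK_INSTANCES)
    def test_p_value_close_to_exact_permutation(self, ta, ea, tb, eb):
        res = logrank(ta, ea, tb, eb)
        perm = logrank_permutation_p(ta + tb, ea + eb, len(ta))
        assert abs(res.p_value - perm) <= 0.02


class TestLogrankTrend:
    def test_three_identical_groups_give_zero(self):
        g = ([10, 20, 30], [1, 1, 1])
        res = logrank_trend([g, g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_with_01_scores_equals_mantel_cox(self):
        ta, ea = [9, 15, 20, 25, 30], [1, 1, 0, 1, 1]
        tb, eb = [6, 8, 12, 16, 28], [1, 1, 1, 0, 1]
        trend = logrank_trend([(ta, ea), (tb, eb)], scores=[0, 1])
        two = logrank(ta, ea, tb, eb)
        assert trend.statistic == pytest.approx(two.statistic, abs=1e-9)
        assert trend.p_value == pytest.approx(two.p_value, abs=1e-9)

    def test_ordered_shift_detected(self):
        groups = [
            ([70, 73, 77, 80], [1, 1, 1, 1]),
            ([63, 66, 70, 73], [1, 1, 1, 1]),
            ([52, 56, 59, 63], [1, 1, 1, 1]),
        ]
        res = logrank_trend(groups)
        assert res.p_value < 0.05

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_trend([([5], [0]), ([6], [0])])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_complete_separation_small_n(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_u_statistics_sum_identity(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=8)
        b = rng.normal(size=6)
        u_a = mann_whitney(a, b).statistic
        u_b = mann_whitney(b, a).statistic
        assert u_a + u_b == pytest.approx(len(a) * len(b))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_mode_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        # tie-free small samples
        pooled = rng.choice(np.arange(100), size=10, replace=False)
        a, b = pooled[:5].tolist(), pooled[5:].tolist()
        res = mann_whitney(a, b)
        assert "exact" in res.method
        assert res.p_value == pytest.approx(mw_exact_p_oracle(a, b), abs=1e-12)

    def test_ties_fall_back_to_midrank_normal_approximation(self):
        res = mann_whitney([63, 63, 66, 70], [70, 70, 73, 77])
        assert "asymptotic" in res.method
        assert 0 <= res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


# ---------------------------------------------------------------------------
# ANOVA / Tukey / Shapiro / summaries
# ---------------------------------------------------------------------------


def _balanced_dataset(seed=11, r=6):
    rng = np.random.default_rng(seed)
    genotype = np.repeat(["WT", "G93A"], 2 * r)
    activity = np.tile(np.repeat(["sedentary", "trained"], r), 2)
    effects = {
        ("WT", "sedentary"): 100.0,
        ("WT", "trained"): 101.0,
        ("G93A", "sedentary"): 80.0,
        ("G93A", "trained"): 52.0,
    }
    values = np.array(
        [effects[(g, a)] for g, a in zip(genotype, activity)]
    ) + rng.normal(0, 6, size=len(genotype))
    return values, genotype, activity


class TestTwoWayAnova:
    def test_matches_closed_form_balanced_oracle(self):
        values, genotype, activity = _balanced_dataset()
        ours = two_way_anova(values, genotype, activity)
        oracle = balanced_anova_oracle(values, genotype, activity)
        for effect in ("genotype", "activity", "interaction"):
            ss, f = oracle[effect]
            assert ours[effect].sum_sq == pytest.approx(ss, abs=1e-8)
            assert ours[effect].F == pytest.approx(f, abs=1e-8)

    def test_affine_invariance_of_f(self):
        values, genotype, activity = _balanced_dataset(seed=2)
        base = two_way_anova(values, genotype, activity)
        shifted = two_way_anova(2.0 * values + 7.0, genotype, activity)
        for effect in base:
            assert shifted[effect].F == pytest.approx(base[effect].F)
            assert shifted[effect].p_value == pytest.approx(base[effect].p_value)

    def test_factor_relabel_invariance(self):
        values, genotype, activity = _balanced_dataset(seed=3)
        base = two_way_anova(values, genotype, activity)
        relabel = {"WT": "zzz", "G93A": "aaa"}
        swapped = two_way_anova(
            values, [relabel[g] for g in genotype], activity
        )
        for effect in base:
            assert swapped[effect].F == pytest.approx(base[effect].F)

    def test_constant_data_has_zero_sums_of_squares(self):
        genotype = ["WT"] * 4 + ["G93A"] * 4
        activity = ["sedentary", "sedentary", "trained", "trained"] * 2
        ours = two_way_anova([5.0] * 8, genotype, activity)
        for effect in ours.values():
            assert effect.sum_sq == pytest.approx(0.0, abs=1e-12)

    def test_sparse_cell_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova(
                [1.0, 2.0, 3.0, 4.0, 5.0],
                ["WT", "WT", "WT", "WT", "G93A"],
                ["sedentary", "sedentary", "trained", "trained", "sedentary"],
            )


class TestTukey:
    def test_detects_the_separated_cell(self):
        values, genotype, activity = _balanced_dataset(seed=4)
        labels = [f"{a[:2]}-{g}" for g, a in zip(genotype, activity)]
        results = tukey_hsd(values, labels)
        assert len(results) == 6  # all pairs of 4 groups
        by_pair = {r.method: r for r in results}
        wt_pair = next(
            r for m, r in by_pair.items()
            if "se-WT" in m and "tr-WT" in m
        )
        g93a_wt = next(
            r for m, r in by_pair.items()
            if "tr-G93A" in m and "se-WT" in m
        )
        assert g93a_wt.p_value < 0.05 < wt_pair.p_value


class TestShapiro:
    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_type_i_error_near_nominal_under_normality(self):
        rng = np.random.default_rng(9)
        rejections = sum(
            shapiro_wilk(rng.normal(size=30)).p_value < 0.05
            for _ in range(300)
        )
        assert 2 <= rejections <= 35  # ~5% nominal

    def test_bimodal_sample_detected(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(50):
            x = np.concatenate(
                [rng.normal(-4, 0.5, 24), rng.normal(4, 0.5, 24)]
            )
            hits += shapiro_wilk(x).p_value < 0.05
        assert hits >= 45  # the vast majority of seeds


class TestGroupSummary:
    def test_hand_example(self):
        (s,) = group_summary({"g": [4.0, 6.0]})
        assert s.mean == pytest.approx(5.0)
        assert s.sem == pytest.approx(1.0)  # sd sqrt(2) / sqrt(2)

    def test_single_value_sem_zero_by_convention(self):
        (s,) = group_summary({"g": [7.0]})
        assert s.sem == 0.0 and s.n == 1

    def test_constant_group(self):
        (s,) = group_summary({"g": [3.0, 3.0, 3.0]})
        assert s.sem == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_summary({"g": []})
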