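import itertools

import numpy as np
import pandas as pd
import pytest

from urostab.errors import (
    DegenerateTestError,
    DesignError,
    UndefinedStatisticError,
)
from urostab.models import (
    decay_model,
    interval_subgroup_analysis,
    mixed_decay_model,
    pearson_r2,
    rank_sum_and_friends,
    wilcoxon_signed_rank,
)


def signed_rank_exact_p(diffs):
    """Enumeration oracle: exact two-sided signed-rank p over all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    n = len(ranks)
    w_obs = ranks[d > 0].sum()
    stats = [
        np.asarray(signs) @ ranks
        for signs in itertools.product([0, 1], repeat=n)
    ]
    stats = np.asarray(stats)
    p_low = (stats <= w_obs + 1e-12).mean()
    p_high = (stats >= w_obs - 1e-12).mean()
    return min(1.0, 2 * min(p_low, p_high))


def rank_sum_exact_p(x, y):
    """Enumeration oracle over all group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    obs = ranks[:n1].sum()
    stats = np.asarray([
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n1)
    ])
    p_low = (stats <= obs + 1e-12).mean()
    p_high = (stats >= obs - 1e-12).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10, dtype=float)
        r2, p = pearson_r2(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_constructed_zero_covariance(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x**2  # symmetric in x -> zero linear correlation
        r2, p = pearson_r2(x, y)
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r2(np.ones(5), np.arange(5.0))


class TestWilcoxonSignedRank:
    def test_all_positive_small(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert res.p_value == pytest.approx(0.25)  # 2 * 1/8
        assert res.method_note.startswith("exact")

    def test_antisymmetric_pair(self):
        res = wilcoxon_signed_rank(np.array([1.0, -1.0]))
        assert res.p_value == pytest.approx(1.0)

    def test_zeros_dropped(self):
        res = wilcoxon_signed_rank(np.array([0.0, 1.0, 2.0, 3.0]))
        assert res.n == (3,)

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank(np.zeros(4))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=rng.integers(5, 13))
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(signed_rank_exact_p(d), abs=1e-12)

    def test_approximation_close_to_enumeration_at_boundary(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.2, 1.0, size=20)
        exact = signed_rank_exact_p(d)
        # force the approximation path by appending tied magnitudes
        tied = np.concatenate([d, [0.5, -0.5]])
        res = wilcoxon_signed_rank(tied)
        assert res.method_note.startswith("normal")
        assert res.p_value == pytest.approx(signed_rank_exact_p(tied), abs=0.01)
        res_exact = wilcoxon_signed_rank(d)
        assert res_exact.p_value == pytest.approx(exact, abs=1e-12)


class TestRankSumAndFriends:
    def test_identical_groups_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = rank_sum_and_friends([x, x + 1e-9], test="wilcoxon_rank_sum")
        assert res.p_value > 0.5

    def test_fully_separated_three_vs_three(self):
        res = rank_sum_and_friends(
            [np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0])],
            test="wilcoxon_rank_sum",
        )
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=5)
        y = rng.normal(0.5, 1, size=6)
        res = rank_sum_and_friends([x, y], test="wilcoxon_rank_sum")
        assert res.p_value == pytest.approx(rank_sum_exact_p(x, y), abs=1e-12)

    def test_kruskal_two_groups_equals_rank_sum_order(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 12)
        kw = rank_sum_and_friends([x, y], test="kruskal_wallis")
        rs = rank_sum_and_friends([x, y], test="wilcoxon_rank_sum")
        # chi-square(1) and two-sided normal mappings agree asymptotically
        assert kw.p_value == pytest.approx(rs.p_value, abs=0.02)

    def test_student_t_runs(self):
        res = rank_sum_and_friends(
            [np.array([1.0, 2.0, 3.0, 4.0]), np.array([3.0, 4.0, 5.0, 6.0])],
            test="student_t",
        )
        assert 0.0 < res.p_value <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_and_friends([np.array([1.0]), np.array([])])


def make_summary(n=40, seed=0, slope=-0.66, intercept=99.78, noise=0.0):
    rng = np.random.default_rng(seed)
    months = rng.uniform(3, 40, n)
    age = rng.uniform(30, 80, n)
    sex = rng.choice(["F", "M"], n)
    cancer = rng.random(n) < 0.4
    response = (intercept + slope * months + rng.normal(0, noise, n)) / 100.0
    return pd.DataFrame(
        dict(
            subject_id=[f"S{i}" for i in range(n)],
            sex=sex,
            age=age,
            cancer=cancer,
            interval_months=months,
            method_combo=rng.choice(["MSU/MSU", "CATHETER/MSU"], n),
            shared_abund_mean=response,
        )
    )


class TestDecayModel:
    def test_noiseless_exact_interpolation(self):
        summary = make_summary(noise=0.0)
        fit = decay_model(summary)
        assert fit.coefficient("intercept")["estimate"] == pytest.approx(99.78, abs=1e-8)
        assert fit.coefficient("months")["estimate"] == pytest.approx(-0.66, abs=1e-10)
        assert fit.coefficient("age")["estimate"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2_marginal == pytest.approx(1.0)

    def test_ci_brackets_estimate_and_df(self):
        summary = make_summary(noise=10.0, seed=3)
        fit = decay_model(summary)
        for _, row in fit.coefficients.iterrows():
            assert row.ci_low <= row.estimate <= row.ci_high
            assert row.df == len(summary) - 5  # intercept + 4 terms

    def test_std_beta_sign_matches_raw(self):
        summary = make_summary(noise=8.0, seed=5)
        fit = decay_model(summary)
        months = fit.coefficient("months")
        assert np.sign(months["std_beta"]) == np.sign(months["estimate"])

    def test_translation_invariance_of_slope(self):
        summary = make_summary(noise=5.0, seed=7)
        shifted = summary.copy()
        shifted["interval_months"] = shifted["interval_months"] + 100.0
        shifted["age"] = shifted["age"] - 50.0
        a = decay_model(summary).coefficient("months")["estimate"]
        b = decay_model(shifted).coefficient("months")["estimate"]
        assert a == pytest.approx(b, abs=1e-9)

    def test_order_invariance(self):
        summary = make_summary(noise=5.0, seed=9)
        shuffled = summary.sample(frac=1.0, random_state=1)
        a = decay_model(summary).coefficient("months")["estimate"]
        b = decay_model(shuffled).coefficient("months")["estimate"]
        assert a == pytest.approx(b)

    def test_collinear_design_raises(self):
        summary = make_summary(seed=11)
        summary["age"] = summary["interval_months"] * 2.0
        with pytest.raises(DesignError, match="aliased|rank"):
            decay_model(summary)

    def test_method_term_supported(self):
        summary = make_summary(noise=4.0, seed=13)
        fit = decay_model(summary, terms=("months", "age", "sex", "cancer", "method"))
        assert "method" in set(fit.coefficients.term)

    def test_mixed_model_rejects_single_row_groups(self):
        summary = make_summary(seed=15)
        with pytest.raises(DesignError, match="unidentifiable"):
            mixed_decay_model(summary)


class TestIntervalSubgroups:
    def test_group_means_and_split(self):
        summary = make_summary(n=60, noise=0.0, seed=17)
        out = interval_subgroup_analysis(summary, split_months=15.0)
        assert out["short"]["n"] + out["long"]["n"] == 60
        # deterministic decline -> short-interval group keeps more abundance
        assert out["short"]["mean_pct"] > out["long"]["mean_pct"]
        assert out["short"]["interval_range"][1] <= 15.0

    def test_no_drift_groups_equal_within_noise(self):
        summary = make_summary(n=80, slope=0.0, noise=3.0, seed=19)
        out = interval_subgroup_analysis(summary, split_months=15.0)
        pooled_sd = max(out["short"]["sd_pct"], out["long"]["sd_pct"])
        assert abs(out["short"]["mean_pct"] - out["long"]["mean_pct"]) < 3 * pooled_sd

    def test_empty_group_raises(self):
        summary = make_summary(n=20, seed=21)
        with pytest.raises(ValueError, match="empty group"):
            interval_subgroup_analysis(summary, split_months=summary.interval_months.min() - 1)
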