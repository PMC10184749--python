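"""Bayes factors, multilevel models, ANOVAs, outlier screening, meta-parameters."""

import numpy as np
import pytest
from scipy import stats as sps

from somatolayers import stats
from somatolayers.core import DegenerateDataError, InvalidArgumentError

from _oracles import jzs_bf_oracle


def paired_data_with_t(t, n, seed=0):
    """Pairs whose difference has exactly the requested paired t statistic."""
    rng = np.random.default_rng(seed)
    d = rng.normal(0, 1, n)
    d = (d - d.mean()) / d.std(ddof=1)          # mean 0, sd 1
    d = d + t / np.sqrt(n)                      # t(d) == t exactly
    x = rng.normal(100, 5, n)
    return x + d, x


class TestJzsBayesFactor:
    def test_null_data_one_sided(self):
        x, y = paired_data_with_t(0.0, 20)
        res = stats.jzs_paired_bf(x, y, side="greater")
        assert res.BF10 < 1
        assert abs(res.BF10 / jzs_bf_oracle(0.0, 20, side="greater") - 1) < 1e-4

    def test_monotone_in_t(self):
        bfs = [stats.jzs_bf_from_t(t, 20, side="greater").BF10
               for t in (1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(bfs) > 0)
        assert bfs[-1] > 1e3

    def test_bf10_bf01_product(self):
        x, y = paired_data_with_t(1.3, 15, seed=2)
        res = stats.jzs_paired_bf(x, y)
        assert np.isclose(res.BF10 * res.BF01, 1.0)

    def test_shift_invariance(self):
        x, y = paired_data_with_t(0.8, 12, seed=3)
        a = stats.jzs_paired_bf(x, y)
        b = stats.jzs_paired_bf(x + 500.0, y + 500.0)
        assert np.isclose(a.BF10, b.BF10, rtol=1e-12)

    @pytest.mark.parametrize("n", [5, 20, 50])
    @pytest.mark.parametrize("t", [0.0, 1.0, -1.0, 2.5, -2.5, 5.0])
    @pytest.mark.parametrize("side", ["two-sided", "greater"])
    def test_oracle_grid(self, n, t, side):
        res = stats.jzs_bf_from_t(t, n, side=side)
        oracle = jzs_bf_oracle(t, n, side=side)
        assert abs(res.BF10 / oracle - 1) < 1e-4

    def test_against_pingouin(self):
        import pingouin as pg
        for t, n in [(0.5, 10), (2.2, 20), (-1.7, 30)]:
            ours = stats.jzs_bf_from_t(t, n, side="two-sided").BF10
            theirs = float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
            assert abs(ours / theirs - 1) < 1e-6

    def test_wrong_direction_bounded_by_two_sided(self):
        x, y = paired_data_with_t(2.0, 20, seed=4)
        wrong = stats.jzs_paired_bf(x, y, side="less").BF10
        two = stats.jzs_paired_bf(x, y, side="two-sided").BF10
        assert wrong <= two

    def test_zero_variance_rejected(self):
        x = np.full(10, 3.0)
        with pytest.raises(DegenerateDataError):
            stats.jzs_paired_bf(x, x)


class TestPriorRobustnessSweep:
    def test_null_data_decreasing_in_scale(self):
        x, y = paired_data_with_t(0.0, 20)
        sweep = stats.prior_robustness_sweep(x, y, side="greater")
        assert np.all(np.diff(sweep.BF10) < 0)
        for r, bf in zip(sweep.prior_scale[::5], sweep.BF10[::5]):
            assert abs(bf / jzs_bf_oracle(0.0, 20, r=r, side="greater") - 1) < 1e-4

    def test_single_scale_consistency(self):
        x, y = paired_data_with_t(1.5, 18, seed=1)
        sweep = stats.prior_robustness_sweep(x, y, scales=[0.707])
        direct = stats.jzs_paired_bf(x, y)
        assert np.isclose(sweep.BF10.iloc[0], direct.BF10)

    def test_strong_effect_everywhere_above_one(self):
        rng = np.random.default_rng(7)
        d = rng.normal(1.5, 1.0, 20)        # effect size ~1.5
        x = rng.normal(0, 1, 20)
        sweep = stats.prior_robustness_sweep(x + d, x, side="greater")
        assert np.all(sweep.BF10 > 1)


class TestMixedModel:
    def test_duplicated_data_equals_ols(self):
        rng = np.random.default_rng(0)
        d = np.tile(np.linspace(0, 1, 30), 4)
        y_single = 5.0 + 2.0 * np.linspace(0, 1, 30) + rng.normal(0, 0.5, 30)
        y = np.tile(y_single, 4)
        pid = np.repeat(np.arange(4), 30)
        fit = stats.fit_mixed_model(y, d, pid)
        ols_slope = np.polyfit(np.linspace(0, 1, 30), y_single, 1)[0]
        assert abs(fit.slope - ols_slope) < 1e-6

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(1)
        pid = np.repeat(np.arange(8), 25)
        d = np.tile(np.linspace(0, 1, 25), 8)
        slopes = 10.0 + rng.normal(0, 2.0, 8)
        y = slopes[pid] * d + rng.normal(0, 1.0, d.size)
        fit = stats.fit_mixed_model(y, d, pid)
        assert fit.ci95[0] <= fit.slope <= fit.ci95[1]
        assert fit.ci95[0] < 10.0 < fit.ci95[1]

    def test_needs_three_participants(self):
        with pytest.raises(InvalidArgumentError):
            stats.fit_mixed_model(np.arange(10.0), np.arange(10.0),
                                  np.repeat([0, 1], 5))


class TestBayesMixedModel:
    def test_conjugate_special_case(self):
        """Known-variance single-level posterior matches the closed form."""
        rng = np.random.default_rng(0)
        n = 60
        d = rng.uniform(0, 1, n)
        y = 1.0 + 4.0 * d + rng.normal(0, 1.0, n)
        fit = stats.bayes_mixed_model(y, d, np.zeros(n, int),
                                      intercept_prior=(0.0, 10.0),
                                      slope_prior=(0.0, 10.0),
                                      sigma2_fixed=1.0, seed=1)
        x = np.column_stack([np.ones(n), d])
        v_n = np.linalg.inv(np.diag([0.01, 0.01]) + x.T @ x)
        m_n = v_n @ (x.T @ y)
        sd_n = np.sqrt(v_n[1, 1])
        draws_sd = (fit.cri95[1] - fit.cri95[0]) / (2 * 1.959963984540054)
        assert abs(fit.posterior_mean - m_n[1]) < 0.02 * max(abs(m_n[1]), 1)
        assert abs(draws_sd / sd_n - 1) < 0.1
        assert fit.n_draws == 4000

    def test_null_slope_concentrates_at_zero(self):
        rng = np.random.default_rng(2)
        pid = np.repeat(np.arange(10), 20)
        d = np.tile(np.linspace(0, 1, 20), 10)
        y = 100.0 + rng.normal(0, 5.0, d.size) + rng.normal(0, 2.0, 10)[pid]
        fit = stats.bayes_mixed_model(y, d, pid, intercept_prior=(100.0, 50.0),
                                      slope_prior=(0.0, 50.0), seed=3)
        assert fit.cri95[0] < 0 < fit.cri95[1]
        assert fit.BF10 < 1
        assert fit.rhat <= 1.01

    def test_retains_4000_draws(self):
        rng = np.random.default_rng(4)
        pid = np.repeat(np.arange(4), 10)
        d = np.tile(np.linspace(0, 1, 10), 4)
        y = d * 2 + rng.normal(0, 1, 40)
        fit = stats.bayes_mixed_model(y, d, pid, seed=5)
        assert fit.n_draws == 4 * 1000


class TestRmAnovaTwoWay:
    def test_two_level_factor_uncorrected(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1, (12, 2, 3))
        res = stats.rm_anova_two_way(data, factors=("layer", "finger"))
        eff = res.effects["layer"]
        assert eff.epsilon == 1.0
        assert eff.correction == "none"

    def test_manual_sums_of_squares(self):
        """F values match hand-computed sums-of-squares on a 4x2x2 table."""
        y = np.array([
            [[3.0, 5.0], [4.0, 7.0]],
            [[2.0, 4.0], [5.0, 6.0]],
            [[4.0, 6.0], [3.0, 8.0]],
            [[3.0, 6.0], [5.0, 7.0]],
        ])
        res = stats.rm_anova_two_way(y, factors=("A", "B"))
        n, a, b = y.shape
        grand = y.mean()
        ss_a = n * b * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
        ss_as = b * ((y.mean(axis=2) - y.mean(axis=(0, 2))[None, :]
                      - y.mean(axis=(1, 2))[:, None] + grand) ** 2).sum()
        f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
        assert abs(res.effects["A"].F - f_a) < 1e-10

    def test_ss_decomposition(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, (9, 3, 4))
        n, a, b = y.shape
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        # reconstruct from the reported etas: eta = SS_eff / SS_total
        res = stats.rm_anova_two_way(y)
        ss_effects = sum(e.eta_squared for e in res.effects.values()) * ss_total
        # remaining: subject + error strata; recompute directly
        subj = a * b * ((y.mean(axis=(1, 2)) - grand) ** 2).sum()
        err_as = b * ((y.mean(axis=2) - y.mean(axis=(0, 2))[None, :]
                       - y.mean(axis=(1, 2))[:, None] + grand) ** 2).sum()
        err_bs = a * ((y.mean(axis=1) - y.mean(axis=(0, 1))[None, :]
                       - y.mean(axis=(1, 2))[:, None] + grand) ** 2).sum()
        ab = ((y.mean(axis=0) - y.mean(axis=(0, 2))[:, None]
               - y.mean(axis=(0, 1))[None, :] + grand) ** 2).sum() * n
        ss_ab_err = ss_total - subj - ss_effects + ab - ab  # sanity anchor
        total_check = ss_effects + subj + err_as + err_bs
        assert total_check <= ss_total + 1e-8
        resid = ss_total - total_check
        assert resid >= -1e-8

    def test_against_pingouin_one_way(self):
        """Collapsing one factor reproduces pingouin's one-way RM ANOVA."""
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, (10, 4, 2)) + np.array([0.0, 0.3, 0.1, -0.2])[None, :, None]
        res = stats.rm_anova_two_way(y, factors=("A", "B"))
        collapsed = y.mean(axis=2)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 4),
            "A": np.tile(np.arange(4), 10),
            "y": collapsed.ravel()})
        pg_res = pg.rm_anova(data=df, dv="y", within="A", subject="subject",
                             correction=True)
        assert abs(res.effects["A"].F - pg_res["F"].iloc[0]) < 1e-8
        assert abs(res.effects["A"].epsilon - pg_res["eps"].iloc[0]) < 1e-8

    def test_missing_cells_rejected(self):
        y = np.full((5, 2, 2), np.nan)
        with pytest.raises(InvalidArgumentError):
            stats.rm_anova_two_way(y)

    def test_posthoc_table(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (8, 3, 2))
        res = stats.rm_anova_two_way(y, posthoc_factor=0)
        assert len(res.posthoc) == 3     # 3 pairwise layer comparisons
        assert np.allclose(res.posthoc.bonferroni_alpha, 0.05 / 3)
        assert np.all(res.posthoc.r.between(0, 1))


class TestTrimmedRmAnova:
    def test_trimmed_mean_arithmetic(self):
        assert stats.trimmed_mean(np.arange(1.0, 11.0), 0.2) == 5.5

    def test_location_shift_power_exceeds_alpha(self):
        rng = np.random.default_rng(0)
        alpha = 0.05
        hits_null, hits_shift = 0, 0
        for _ in range(200):
            base = rng.normal(0, 1, (20, 3))
            hits_null += stats.trimmed_rm_anova(base).effects["level"].p < alpha
            shifted = base.copy()
            shifted[:, 2] += 1.0
            hits_shift += stats.trimmed_rm_anova(shifted).effects["level"].p < alpha
        assert hits_shift / 200 > hits_null / 200
        assert hits_shift / 200 > 0.5

    def test_invalid_trim(self):
        with pytest.raises(InvalidArgumentError):
            stats.trimmed_rm_anova(np.zeros((10, 3)), trim=0.5)

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            stats.trimmed_rm_anova(np.zeros((4, 3)))


class TestExtremeOutliers:
    def test_single_outlier(self):
        mask = stats.extreme_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert list(mask) == [False, False, False, False, True]

    def test_constant_sample(self):
        assert not stats.extreme_outliers(np.full(10, 2.0)).any()

    def test_normal_sample_rate(self):
        rng = np.random.default_rng(0)
        mask = stats.extreme_outliers(rng.normal(0, 1, 10_000))
        assert mask.mean() < 0.001


class TestProfileMeta:
    def test_symmetric_profile_zero_skew(self):
        # values form a multiset symmetric about the center depth's value
        v = 1800.0 + 10.0 * np.arange(-10.0, 11.0)
        rng = np.random.default_rng(0)
        rng.shuffle(v)   # skewness ignores the depth ordering
        skew, _ = stats.profile_meta(v)
        assert abs(skew) < 1e-12

    def test_right_tail_positive_skew(self):
        skew, _ = stats.profile_meta([1.0, 1.0, 1.0, 10.0])
        assert skew > 0

    def test_large_normal_sample_excess_kurtosis(self):
        rng = np.random.default_rng(1)
        _, kurt = stats.profile_meta(rng.normal(0, 1, 100_000))
        assert abs(kurt) < 0.1

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            stats.profile_meta(np.full(21, 5.0))
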