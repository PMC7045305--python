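"""Inferential tests against hand computations and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vppipe.stats import (
    StatResult,
    chi_square,
    mixed_anova,
    newman_keuls,
    one_sample_t,
    paired_t,
    rm_anova,
)


def gg_anova_oracle(Y):
    """From-scratch one-way RM-ANOVA with Greenhouse–Geisser epsilon."""
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    grand = Y.mean()
    ss_cond = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((Y - grand) ** 2).sum() - ss_cond - ss_subj
    F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    sigma = np.cov(Y, rowvar=False, ddof=1)
    C = np.eye(k) - np.ones((k, k)) / k
    S = C @ sigma @ C
    eps = np.trace(S) ** 2 / ((k - 1) * np.trace(S @ S))
    p = sps.f.sf(F, eps * (k - 1), eps * (k - 1) * (n - 1))
    return F, eps, p


class TestTTests:
    def test_identical_pairs_give_null_result(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_paired_t_hand_computation(self):
        # differences (1, 2, 3): t = 2*sqrt(3), df = 2
        r = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(2 * np.sqrt(3))
        assert r.df == 2

    def test_df_contract_seven_pairs(self):
        rng = np.random.default_rng(0)
        r = paired_t(rng.normal(size=7), rng.normal(size=7))
        assert r.df == 6

    def test_one_sample_hand_computation(self):
        r = one_sample_t([1.0, 2.0, 3.0], mu=0.0)
        assert r.statistic == pytest.approx(2 * np.sqrt(3))
        assert r.df == 2

    def test_one_sample_mean_equals_mu(self):
        assert one_sample_t([1.0, 2.0, 3.0], mu=2.0).statistic == pytest.approx(0.0)

    def test_shuffle_null_df_contract(self):
        r = one_sample_t(np.random.default_rng(1).normal(size=1000), mu=0.0)
        assert r.df == 999


class TestRmAnova:
    def test_constant_conditions_give_zero_f(self):
        Y = np.tile(np.random.default_rng(2).normal(size=(6, 1)), (1, 4))
        r = rm_anova(Y)
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_two_levels_epsilon_one_and_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r = rm_anova(np.column_stack([x, y]))
        t = paired_t(x, y)
        assert r.epsilon == pytest.approx(1.0)
        assert r.statistic == pytest.approx(t.statistic**2)

    def test_matches_from_scratch_gg_oracle(self):
        Y = np.random.default_rng(4).normal(size=(5, 3)) + np.array([0.0, 0.4, 0.9])
        r = rm_anova(Y)
        F, eps, p = gg_anova_oracle(Y)
        assert r.statistic == pytest.approx(F)
        assert r.epsilon == pytest.approx(eps)
        assert r.p == pytest.approx(p, rel=1e-6)
        assert r.df[0] == pytest.approx(eps * 2)

    def test_epsilon_bounds(self):
        for seed in range(10):
            Y = np.random.default_rng(seed).normal(size=(8, 4))
            r = rm_anova(Y)
            assert 1.0 / 3.0 - 1e-9 <= r.epsilon <= 1.0 + 1e-9

    def test_missing_cells_rejected(self):
        Y = np.random.default_rng(5).normal(size=(5, 3))
        Y[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova(Y)

    def test_mixed_design_reports_all_sources(self):
        rng = np.random.default_rng(6)
        rows = []
        for g, group in enumerate(["Glu", "GABA"]):
            for s in range(6):
                for c, cond in enumerate(["Ext1", "Ext10", "Reinst"]):
                    rows.append(
                        {"subject": f"{group}{s}", "group": group, "cond": cond,
                         "y": rng.normal() + 0.8 * g * c}
                    )
        out = mixed_anova(pd.DataFrame(rows))
        assert {"group", "cond", "interaction"} <= set(out.keys())
        inter = out["interaction"]
        assert inter.correction == "GG" and 0.5 <= inter.epsilon <= 1.0


class TestNewmanKeuls:
    def test_equal_means_nothing_significant(self):
        res = newman_keuls([1.0, 1.0, 1.0], ms_error=1.0, df_error=12, n_per_group=5)
        assert not res["significant"].any()

    def test_two_groups_reduce_to_t_comparison(self):
        # q = t*sqrt(2): the SNK p for two groups equals the two-sided
        # pooled-t p computed through the studentized range with r = 2
        means, mse, df, n = [1.0, 2.0], 1.3, 10, 6
        res = newman_keuls(means, mse, df, n)
        t = (means[1] - means[0]) / np.sqrt(2 * mse / n)
        expected = 2 * sps.t.sf(abs(t), df)
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-4)

    def test_q_distribution_against_monte_carlo(self):
        # CDF of the studentized range at q=3, k=3, df=10 vs brute force
        rng = np.random.default_rng(7)
        z = rng.normal(size=(1_000_000, 3))
        s = np.sqrt(rng.chisquare(10, size=1_000_000) / 10)
        q = (z.max(axis=1) - z.min(axis=1)) / s
        mc = (q <= 3.0).mean()
        assert sps.studentized_range.cdf(3.0, 3, 10) == pytest.approx(mc, abs=0.005)

    def test_nonsignificance_propagates_inside_spans(self):
        # wide span barely non-significant blocks the inner pair
        res = newman_keuls([0.0, 0.01, 0.02, 5.0], ms_error=1.0, df_error=8, n_per_group=4)
        res = res.set_index(["group_a", "group_b"])
        assert not res.loc[(0, 1), "significant"]
        assert res.loc[(0, 1), "p"] >= res.loc[(0, 2), "p_raw"] - 1e-12


class TestChiSquare:
    def test_independent_table_gives_zero(self):
        margins = np.outer([30, 70], [40, 60]) // 1
        r = chi_square(margins.astype(int))
        assert r.statistic == pytest.approx(0.0)

    def test_hand_computed_2x2(self):
        r = chi_square(np.array([[10, 20], [20, 10]]))
        assert r.statistic == pytest.approx(20.0 / 3.0, rel=1e-6)
        assert r.df == 1

    def test_bonferroni_clamps_at_one(self):
        table = np.array([[12, 10], [11, 13]])
        r = chi_square(table, bonferroni_m=5)
        assert r.p == min(1.0, 5 * r.p_uncorrected)

    def test_closed_form_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            obs = rng.integers(1, 1000, size=(2, 2))
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            oracle = ((obs - expected) ** 2 / expected).sum()
            assert chi_square(obs).statistic == pytest.approx(oracle, rel=1e-10)

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square(np.array([[1.5, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            chi_square(np.array([[-1, 2], [2, 1]]))


class TestTypeICalibration:
    """Under their null, all tests reject at ~alpha (95% binomial band)."""

    @staticmethod
    def _band(n, alpha=0.05):
        half = 1.96 * np.sqrt(alpha * (1 - alpha) / n)
        return alpha - half, alpha + half

    def test_paired_t_calibrated(self):
        rng = np.random.default_rng(9)
        rej = np.mean(
            [paired_t(rng.normal(size=10), rng.normal(size=10)).p < 0.05 for _ in range(400)]
        )
        lo, hi = self._band(400)
        assert lo <= rej <= hi

    def test_one_sample_t_calibrated(self):
        rng = np.random.default_rng(10)
        rej = np.mean([one_sample_t(rng.normal(size=12), 0.0).p < 0.05 for _ in range(400)])
        lo, hi = self._band(400)
        assert lo <= rej <= hi

    def test_rm_anova_gg_calibrated_under_sphericity(self):
        rng = np.random.default_rng(11)
        rej = np.mean([rm_anova(rng.normal(size=(10, 3))).p < 0.05 for _ in range(250)])
        lo, hi = self._band(250)
        # GG is mildly conservative when sphericity holds
        assert rej <= hi and rej >= lo - 0.02

    def test_chi_square_calibrated_on_multinomial_null(self):
        rng = np.random.default_rng(12)
        hits = []
        for _ in range(400):
            row = rng.random() * 0.4 + 0.3
            col = rng.random() * 0.4 + 0.3
            p = np.array([[row * col, row * (1 - col)], [(1 - row) * col, (1 - row) * (1 - col)]])
            table = rng.multinomial(500, p.ravel()).reshape(2, 2)
            hits.append(chi_square(table).p < 0.05)
        lo, hi = self._band(400)
        assert lo <= np.mean(hits) <= hi


def test_stat_result_validates_p():
    with pytest.raises(ValueError):
        StatResult("x", 1.0, 1, 1.5)
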