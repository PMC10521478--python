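"""Closed-form statistics vs independent scipy/statsmodels oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from evlongread.stats import (
    bin_lengths,
    chi_square_2x2,
    pearson_r,
    two_way_anova_lengths,
    welch_t,
)


class TestWelchT:
    def test_identical_samples(self):
        result = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_hand_computed_example(self):
        result = welch_t([1, 2, 3], [4, 5, 6])
        assert result.statistic == pytest.approx(-3 / math.sqrt(2 / 3), abs=1e-12)
        assert result.df == pytest.approx(4.0, abs=1e-12)

    def test_scale_invariance(self):
        a = welch_t([1.0, 2.0, 4.0], [3.0, 5.0, 9.0])
        b = welch_t([10.0, 20.0, 40.0], [30.0, 50.0, 90.0])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_zero_variance_both_equal_means(self):
        result = welch_t([2.0, 2.0], [2.0, 2.0])
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_zero_variance_unequal_means_limit(self):
        result = welch_t([2.0, 2.0], [3.0, 3.0])
        assert result.statistic == -math.inf and result.p_value == 0.0

    def test_against_scipy_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.normal(0, 1 + rng.random(), size=rng.integers(3, 20))
            y = rng.normal(rng.normal(), 1 + rng.random(), size=rng.integers(3, 20))
            ours = welch_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_pooled_matches_student(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=8), rng.normal(size=5)
        ours = welch_t(x, y, pooled=True)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestChiSquare:
    def test_proportional_table_is_null(self):
        result = chi_square_2x2([[10, 20], [30, 60]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        # E = [[30,70],[30,70]]; sum (O-E)^2/E = 2*(100/30 + 100/70)
        result = chi_square_2x2([[40, 60], [20, 80]])
        assert result.statistic == pytest.approx(200 / 30 + 200 / 70, abs=1e-12)

    def test_transpose_invariance(self):
        a = chi_square_2x2([[40, 60], [20, 80]])
        b = chi_square_2x2([[40, 20], [60, 80]])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 10]])

    @pytest.mark.parametrize("yates", [False, True])
    def test_against_scipy_on_random_instances(self, yates):
        rng = np.random.default_rng(13)
        for _ in range(100):
            table = rng.integers(1, 200, size=(2, 2))
            ours = chi_square_2x2(table, yates=yates)
            stat, p, _, _ = sps.chi2_contingency(table, correction=yates)
            assert ours.statistic == pytest.approx(stat, abs=1e-8)
            assert ours.p_value == pytest.approx(p, abs=1e-8)


class TestPearson:
    def test_exact_lines(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, x).r == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_five_point_toy_vs_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 10.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson_r(x, y).r == pytest.approx(num / den, abs=1e-14)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_against_scipy_on_random_instances(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            ours = pearson_r(x, y)
            ref = sps.pearsonr(x, y)
            assert ours.r == pytest.approx(ref.statistic, abs=1e-8)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-8)


def _anova_frame(rng, n_groups=2, n_bins=3, n_reps=2, group_effect=0.0):
    rows = []
    for g in range(n_groups):
        for rep in range(n_reps):
            for b in range(n_bins):
                rows.append(
                    {
                        "sample": f"g{g}_s{rep}",
                        "group": f"g{g}",
                        "bin": f"b{b}",
                        "value": rng.normal(b * 0.1 + g * group_effect, 0.05),
                    }
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_distributions_give_null(self):
        rows = []
        for g in ("Exo", "MV"):
            for rep in range(3):
                for i, v in enumerate([0.5, 0.3, 0.2]):
                    rows.append(
                        {"sample": f"{g}{rep}", "group": g, "bin": f"b{i}", "value": v}
                    )
        result = two_way_anova_lengths(pd.DataFrame(rows))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0, abs=1e-12)

    def test_small_toy_matches_hand_ss_decomposition(self):
        data = _anova_frame(np.random.default_rng(5), group_effect=0.2)
        result = two_way_anova_lengths(data)
        y = data["value"].to_numpy()
        grand = y.mean()
        ss_g = sum(
            len(sub) * (sub["value"].mean() - grand) ** 2
            for _, sub in data.groupby("group")
        )
        ss_b = sum(
            len(sub) * (sub["value"].mean() - grand) ** 2
            for _, sub in data.groupby("bin")
        )
        ss_res = ((y - grand) ** 2).sum() - ss_g - ss_b
        df_res = len(y) - (2 - 1) - (3 - 1) - 1
        assert result.statistic == pytest.approx((ss_g / 1) / (ss_res / df_res), abs=1e-10)

    def test_label_permutation_within_group_invariance(self):
        data = _anova_frame(np.random.default_rng(6), group_effect=0.1)
        shuffled = data.copy()
        mask = shuffled["sample"] == "g0_s0"
        shuffled.loc[mask, "sample"] = "g0_sX"
        assert two_way_anova_lengths(shuffled).statistic == pytest.approx(
            two_way_anova_lengths(data).statistic, abs=1e-12
        )

    def test_empty_cell_errors_naming_the_cell(self):
        data = _anova_frame(np.random.default_rng(7))
        data = data[~((data["group"] == "g1") & (data["bin"] == "b2"))]
        with pytest.raises(ValueError, match="g1.*b2"):
            two_way_anova_lengths(data)

    def test_against_statsmodels_on_random_balanced_instances(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            data = _anova_frame(
                rng,
                n_groups=int(rng.integers(2, 4)),
                n_bins=int(rng.integers(2, 5)),
                n_reps=int(rng.integers(2, 4)),
                group_effect=float(rng.normal(0, 0.1)),
            )
            ours = two_way_anova_lengths(data)
            model = ols("value ~ C(group) + C(bin)", data=data).fit()
            table = sm.stats.anova_lm(model, typ=2)
            assert ours.statistic == pytest.approx(table.loc["C(group)", "F"], abs=1e-8)
            assert ours.p_value == pytest.approx(table.loc["C(group)", "PR(>F)"], abs=1e-8)


class TestBinLengths:
    def test_bins_and_overflow(self):
        props = bin_lengths([50, 250, 1999, 2000, 5000])
        assert props.sum() == pytest.approx(1.0)
        assert props["[0,200)"] == pytest.approx(0.2)
        assert props["[1800,2000)"] == pytest.approx(0.2)
        assert props[">=2000"] == pytest.approx(0.4)
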