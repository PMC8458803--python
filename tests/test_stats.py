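"""Nonparametric test battery: rank-sum, Fisher, chi-square, Spearman, Bonferroni."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from natsc import (
    bonferroni,
    chi2_test,
    compare_groups,
    fisher_exact,
    rank_sum_test,
    spearman,
)
from natsc.stats import categorical_test, chi2_statistic


class TestRankSum:
    def test_fully_separated_small_samples(self):
        # 20 equally likely rank splits; only the two extreme ones are as extreme
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(2 / 20)

    def test_identical_samples_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 6)
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a))

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (6, 6), (2, 9)])
    def test_exact_path_matches_scipy_exact_distribution(self, na, nb):
        # independent oracle: scipy's exact Mann-Whitney distribution (no ties)
        rng = np.random.default_rng(na * 13 + nb)
        for _ in range(10):
            a = rng.permutation(np.arange(1.0, na + nb + 1))[:na]
            b = np.setdiff1d(np.arange(1.0, na + nb + 1), a)
            mine = rank_sum_test(a, b)
            oracle = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert mine == pytest.approx(float(oracle), abs=1e-12)

    def test_exact_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        p1 = rank_sum_test(a, b)
        p2 = rank_sum_test(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def _fisher_oracle(table):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_study_sex_table_rounds_to_020(self):
        # 8 M / 2 F patients vs 6 M / 6 F controls
        assert round(fisher_exact([[8, 2], [6, 6]]), 2) == 0.20

    def test_balanced_table_gives_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            t = rng.integers(0, 11, (2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact(t) == pytest.approx(_fisher_oracle(t), abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


class TestChi2:
    def test_table_equal_to_expected_gives_p_one(self):
        assert chi2_test([[10, 10], [10, 10]]) == pytest.approx(1.0)
        assert chi2_statistic([[10, 10], [10, 10]]) == pytest.approx(0.0)

    def test_statistic_matches_hand_computation_2x3(self):
        obs = np.array([[10.0, 20.0, 30.0], [20.0, 20.0, 20.0]])
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        oracle = float(np.sum((obs - expected) ** 2 / expected))
        assert chi2_statistic(obs) == pytest.approx(oracle, rel=1e-12)
        assert chi2_test(obs) == pytest.approx(float(sps.chi2.sf(oracle, 2)), rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_test([[0, 0], [1, 2]])

    def test_policy_uses_fisher_for_sparse_2x2(self):
        t = [[2, 1], [1, 3]]
        assert categorical_test(t) == pytest.approx(fisher_exact(t))
        big = [[20, 30], [25, 25]]
        assert categorical_test(big) == pytest.approx(chi2_test(big))


class TestSpearman:
    def test_monotone_increasing_gives_rho_one(self):
        x = np.arange(1.0, 8.0)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.arange(1.0, 8.0)
        rho, _ = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 8.0, 7.0, 9.0, 9.0])
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(float(oracle), rel=1e-12)

    def test_small_sample_p_is_exact_permutation_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = spearman(x, y)
        from itertools import permutations as perms

        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rhos = [np.corrcoef(rx, np.array(pm))[0, 1] for pm in perms(ry)]
        p_oracle = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert rho == pytest.approx(float(sps.spearmanr(x, y).statistic))
        assert p == pytest.approx(float(p_oracle))

    def test_constant_input_flagged_as_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(rho) and math.isnan(p)

    def test_length_mismatch_and_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


class TestBonferroni:
    def test_six_roi_family_displays_0008(self):
        r = bonferroni(0.05, 6)
        assert r.display_threshold == 0.008
        assert r.corrected_threshold == pytest.approx(0.05 / 6)

    def test_single_comparison_keeps_alpha(self):
        assert bonferroni(0.05, 1).corrected_threshold == 0.05

    def test_flags_are_monotone_in_alpha(self):
        ps = (0.004, 0.007, 0.009, 0.02)
        loose = bonferroni(0.05, 6, ps).flags
        tight = bonferroni(0.01, 6, ps).flags
        assert all(not t or l for l, t in zip(loose, tight))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni(1.5, 6)
        with pytest.raises(ValueError):
            bonferroni(0.05, 6, (1.2,))


def _cohort_frame(rng, n_ipd=10, n_hc=12, shift=None):
    from natsc import default_group_params
    from natsc.phantom import ROI_NAMES

    params = default_group_params()
    rows = []
    for grp, n in (("iPD", n_ipd), ("HC", n_hc)):
        for i in range(n):
            row = {"subject_id": f"{grp}{i}", "group": grp}
            for roi in ROI_NAMES:
                mean, sd = params["HC"][roi]
                if shift and grp == "iPD":
                    mean, sd = params["iPD"][roi]
                row[f"{roi}_tsc"] = rng.normal(mean, sd)
                row[f"{roi}_nvol"] = rng.normal(0.5, 0.1)
            rows.append(row)
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_high_powered_sn_difference_flagged(self):
        rng = np.random.default_rng(0)
        cohort = _cohort_frame(rng, n_ipd=200, n_hc=200, shift=True)
        res = compare_groups(cohort)
        sn = res.table[(res.table.roi == "SN") & (res.table.measure == "tsc")].iloc[0]
        assert sn["significant_after_bonferroni"]

    def test_single_measure_projection(self):
        rng = np.random.default_rng(1)
        res = compare_groups(_cohort_frame(rng), measures=("tsc",))
        assert set(res.table["measure"]) == {"tsc"}
        assert len(res.table) == 6

    def test_group_with_fewer_than_two_subjects_rejected(self):
        rng = np.random.default_rng(2)
        cohort = _cohort_frame(rng, n_ipd=1, n_hc=12)
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups(cohort)

    def test_means_and_sds_reported_per_group(self):
        rng = np.random.default_rng(3)
        cohort = _cohort_frame(rng)
        res = compare_groups(cohort)
        row = res.table[(res.table.roi == "SN") & (res.table.measure == "tsc")].iloc[0]
        vals = cohort.loc[cohort.group == "iPD", "SN_tsc"]
        assert row["mean_ipd"] == pytest.approx(vals.mean())
        assert row["sd_ipd"] == pytest.approx(vals.std(ddof=1))
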