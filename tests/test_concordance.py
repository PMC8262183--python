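"""Agreement statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ihctps.concordance import (
    DegenerateInputError,
    JoinError,
    agreement_vs_gold,
    bland_altman,
    category_distribution_test,
    cohens_kappa,
    interpret_kappa,
    kappa_detectable_difference,
    kappa_power,
    lin_ccc,
    paired_difference_tests,
)


def brute_force_kappa(table):
    """Kappa recomputed from reconstructed per-item label pairs."""
    table = np.asarray(table, dtype=int)
    pairs = [
        (i, j)
        for i in range(table.shape[0])
        for j in range(table.shape[1])
        for _ in range(table[i, j])
    ]
    n = len(pairs)
    po = sum(i == j for i, j in pairs) / n
    row = np.bincount([i for i, _ in pairs], minlength=table.shape[0]) / n
    col = np.bincount([j for _, j in pairs], minlength=table.shape[1]) / n
    pe = float(np.sum(row * col))
    if pe >= 1.0 - 1e-15:
        return None
    return (po - pe) / (1 - pe)


def brute_force_chi2(table):
    """Pearson chi-squared by explicit expected-count loops."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    return stat


class TestLinCCC:
    def test_identity_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = lin_ccc(x, x)
        assert res.estimate == pytest.approx(1.0)

    def test_constant_shift_penalized_below_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 10, 100)
        y = x + 10
        res = lin_ccc(x, y)
        assert res.estimate < 1.0
        assert stats.pearsonr(x, y)[0] == pytest.approx(1.0)

    def test_matches_direct_formula_to_1e12(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(30, 15, 50)
            y = 0.8 * x + rng.normal(0, 5, 50) + 3
            n = len(x)
            sxy = np.sum((x - x.mean()) * (y - y.mean())) / n
            expected = 2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)
            assert lin_ccc(x, y).estimate == pytest.approx(expected, abs=1e-12)

    def test_magnitude_bounded_by_pearson(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0.5, 2, 40)
            r = stats.pearsonr(x, y)[0]
            assert abs(lin_ccc(x, y).estimate) <= abs(r) + 1e-12

    def test_invariant_to_common_shift(self):
        rng = np.random.default_rng(13)
        x = rng.normal(10, 3, 60)
        y = rng.normal(11, 3, 60)
        a = lin_ccc(x, y).estimate
        b = lin_ccc(x + 42.5, y + 42.5).estimate
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(DegenerateInputError):
            lin_ccc(np.ones(5), np.ones(5))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(30, 10, 80)
        y = x + rng.normal(0, 4, 80)
        res = lin_ccc(x, y)
        assert res.ci_low < res.estimate < res.ci_high
        assert -1 <= res.ci_low and res.ci_high <= 1


class TestCohensKappa:
    def test_diagonal_table_kappa_one(self):
        assert cohens_kappa(np.diag([10, 20])).estimate == pytest.approx(1.0)

    def test_chance_agreement_kappa_zero(self):
        # counts proportional to marginal products
        table = np.outer([40, 60], [30, 70]) / 100.0
        assert cohens_kappa(table).estimate == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        res = cohens_kappa([[50, 10], [10, 30]])
        # po = 0.8, pe = (60*60 + 40*40)/100^2 = 0.52
        assert res.estimate == pytest.approx((0.8 - 0.52) / 0.48, abs=1e-12)

    def test_exhaustive_small_tables_match_brute_force(self):
        """All 2x2 integer tables with total <= 30 vs a reconstruction oracle."""
        checked = 0
        for total in range(1, 31):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        table = [[a, b], [c, d]]
                        expected = brute_force_kappa(table)
                        if expected is None:
                            with pytest.raises(DegenerateInputError):
                                cohens_kappa(table)
                        else:
                            assert cohens_kappa(table).estimate == pytest.approx(
                                expected, abs=1e-10
                            )
                            checked += 1
        assert checked > 1000

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        table = np.array([[50, 10], [7, 33]])
        ours = cohens_kappa(table)
        theirs = sm_kappa(table, return_results=True)
        assert ours.estimate == pytest.approx(float(theirs.kappa), abs=1e-12)

    def test_interpretation_bands(self):
        assert interpret_kappa(0.95) == "near perfect"
        assert interpret_kappa(0.85) == "strong"
        assert interpret_kappa(0.75) == "moderate"
        assert interpret_kappa(0.5) == "weak"
        assert interpret_kappa(0.2) == "minimal or none"


class TestAgreementVsGold:
    def test_perfect_agreement(self):
        s = pd.Series([0.5, 10, 60, 80], index=list("abcd"))
        rep = agreement_vs_gold(s, s, 50.0)
        assert rep.percent_concordance == 100.0
        assert rep.kappa.estimate == pytest.approx(1.0)
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0

    def test_all_positives_flipped_zero_sensitivity(self):
        gold = pd.Series([60.0, 70.0, 10.0, 5.0], index=list("abcd"))
        method = pd.Series([10.0, 20.0, 10.0, 5.0], index=list("abcd"))
        rep = agreement_vs_gold(method, gold, 50.0)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 100.0

    def test_id_mismatch_raises_join_error(self):
        with pytest.raises(JoinError):
            agreement_vs_gold(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"]), 1.0
            )

    def test_recovers_programmed_flip_rates(self):
        """Simulated rater with known sensitivity/specificity vs gold."""
        rng = np.random.default_rng(77)
        n = 2000
        gold_positive = rng.random(n) < 0.4
        sens_true, spec_true = 0.9, 0.8
        called = np.where(
            gold_positive, rng.random(n) < sens_true, rng.random(n) >= spec_true
        )
        gold = pd.Series(np.where(gold_positive, 60.0, 10.0), index=range(n))
        method = pd.Series(np.where(called, 60.0, 10.0), index=range(n))
        rep = agreement_vs_gold(method, gold, 50.0)
        # binomial 95% margins at n ~ 800/1200 per class
        assert rep.sensitivity / 100 == pytest.approx(sens_true, abs=0.035)
        assert rep.specificity / 100 == pytest.approx(spec_true, abs=0.035)


class TestRankTests:
    def test_identical_paired_degenerate_p1(self):
        res = paired_difference_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_constant_shift_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        res = paired_difference_tests(x + 2.0, x)
        assert res.p_value < 0.001

    def test_wilcoxon_matches_enumeration_oracle(self):
        """Exact two-sided p by enumerating all sign assignments (n <= 10)."""
        rng = np.random.default_rng(6)
        for n in (6, 8, 10):
            d = rng.normal(0.4, 1.0, n)
            while len(np.unique(np.abs(d))) < n or np.any(d == 0):
                d = rng.normal(0.4, 1.0, n)
            ranks = stats.rankdata(np.abs(d))
            tplus = ranks[d > 0].sum()
            mu = ranks.sum() / 2
            dist = np.array(
                [
                    sum(r for s, r in zip(signs, ranks) if s)
                    for signs in itertools.product([0, 1], repeat=n)
                ]
            )
            p_oracle = np.mean(np.abs(dist - mu) >= abs(tplus - mu) - 1e-9)
            res = paired_difference_tests(d, np.zeros(n))
            assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_mann_whitney_independent_mode(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40)
        y = rng.normal(1.5, 1, 40)
        res = paired_difference_tests(x, y, paired=False)
        assert res.p_value < 0.001


class TestChiSquared:
    def test_identical_distributions_zero_statistic(self):
        stat, p = category_distribution_test([[10, 20, 30], [10, 20, 30]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x3(self):
        table = [[10, 20, 30], [20, 20, 20]]
        stat, p = category_distribution_test(table)
        assert stat == pytest.approx(brute_force_chi2(table), abs=1e-12)
        assert stat == pytest.approx(16.0 / 3.0, abs=1e-12)

    def test_exhaustive_small_tables_match_brute_force(self):
        """All 2x2 tables with positive margins and total <= 30."""
        checked = 0
        for total in range(4, 31):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        t = np.array([[a, b], [c, d]])
                        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                            continue
                        stat, _ = category_distribution_test(t)
                        assert stat == pytest.approx(brute_force_chi2(t), abs=1e-9)
                        checked += 1
        assert checked > 1000

    def test_mid_category_inflation_detected_at_study_scale(self):
        """Power: shifting scores into the middle category is detectable.

        The automated-vs-manual pattern: some sub-1%% patches called 1-49
        and some >=50 patches called 1-49, at roughly the observed rates,
        n = 207 patches per method.
        """
        rng = np.random.default_rng(19)
        hits = 0
        runs = 60
        for _ in range(runs):
            gold = rng.choice([0, 1, 2], size=207, p=[0.45, 0.30, 0.25])
            auto = gold.copy()
            low = np.nonzero(auto == 0)[0]
            high = np.nonzero(auto == 2)[0]
            auto[rng.choice(low, size=min(16, len(low)), replace=False)] = 1
            auto[rng.choice(high, size=min(16, len(high)), replace=False)] = 1
            table = np.stack(
                [np.bincount(gold, minlength=3), np.bincount(auto, minlength=3)]
            )
            _, p = category_distribution_test(table)
            hits += p < 0.05
        assert hits / runs >= 0.8


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.mean_difference == 0.0
        assert ba.lower_limit == ba.upper_limit == 0.0

    def test_constant_offset(self):
        x = np.array([10.0, 20.0, 30.0])
        ba = bland_altman(x, x - 5)
        assert ba.mean_difference == pytest.approx(5.0)
        assert ba.sd_difference == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        x = rng.normal(50, 10, 200)
        y = rng.normal(48, 12, 200)
        ba = bland_altman(x, y)
        d = x - y
        assert ba.mean_difference == pytest.approx(d.mean(), abs=1e-12)
        assert ba.sd_difference == pytest.approx(d.std(ddof=1), abs=1e-12)
        assert ba.upper_limit == pytest.approx(d.mean() + 2 * d.std(ddof=1), abs=1e-12)


class TestKappaPower:
    def test_study_scale_detectable_difference(self):
        """n=207 patches, sd 0.4: minimum detectable kappa difference 0.11."""
        assert round(kappa_detectable_difference(207, 0.4, 0.05, 0.80), 2) == 0.11

    def test_case_level_power(self):
        """n=69 cases, d=0.15: power 0.6 to one decimal."""
        assert round(kappa_power(69, 0.4, 0.05, 0.15), 1) == 0.6

    def test_power_half_limit(self):
        d = kappa_detectable_difference(100, 0.4, 0.05, 0.5 + 1e-12)
        expected = stats.norm.ppf(0.975) * 0.4 * np.sqrt(2 / 100)
        assert d == pytest.approx(expected, abs=1e-6)

    def test_zero_difference_null_power(self):
        assert kappa_power(100, 0.4, 0.05, 0.0) == pytest.approx(0.025)

    def test_inverse_consistency(self):
        """kappa_power at the detectable difference returns the target power."""
        for n, power in ((50, 0.7), (207, 0.8), (500, 0.9)):
            d = kappa_detectable_difference(n, 0.4, 0.05, power)
            assert kappa_power(n, 0.4, 0.05, d) == pytest.approx(power, abs=1e-9)

    def test_monotone_in_n_and_d(self):
        assert kappa_power(200, d=0.1) > kappa_power(100, d=0.1)
        assert kappa_power(100, d=0.2) > kappa_power(100, d=0.1)
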