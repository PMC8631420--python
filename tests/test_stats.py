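"""Frequency tables and inferential statistics against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest

from vigitext.labels import SYMPTOMS, label_vector
from vigitext.stats import (
    FrequencyTable,
    correlation,
    fisher_exact_2x2,
    fit_age_slope,
    format_p,
    frequency_table,
    mann_whitney_compare,
    prevalence_ratio,
    shapiro_wilk,
)

# Published over-60 comparison columns (trial n=1029 vs self-reports n=690)
TRIAL_N, TELEGRAM_N = 1029, 690
COMPARISON_ROWS = {
    # category: (trial_count, telegram_count, expected_prevalence_ratio)
    "headache": (30, 89, 4.42),
    "fatigue": (31, 141, 6.78),
    "nausea": (12, 9, 1.12),
    "erythema": (39, 15, 0.57),
    "diarrhea": (8, 3, 0.56),
}


class TestFrequencyTable:
    def test_empty_input_gives_zero_counts(self):
        table = frequency_table([], denominator=10)
        assert table.counts.sum() == 0
        assert table.denominator == 10

    def test_published_fever_percentage(self):
        table = FrequencyTable(("fever",), np.array([5461]), 11_515)
        assert table.percentages[0] == pytest.approx(47.43, abs=0.005)

    def test_counts_equal_brute_force_column_sums(self):
        rng = np.random.default_rng(0)
        mat = rng.random((200, 12)) < 0.3
        table = frequency_table(mat, denominator=250)
        for j, cls in enumerate(SYMPTOMS):
            assert table.counts[j] == sum(row[j] for row in mat)

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            frequency_table([], denominator=0)
        with pytest.raises(ValueError):
            frequency_table([label_vector(["fever"])] * 5, denominator=3)

    def test_csv_round_trip(self, tmp_path):
        table = frequency_table([label_vector(["fever", "pain"])] * 3, 10)
        path = tmp_path / "freq.csv"
        table.to_csv(path)
        back = FrequencyTable.from_csv(path)
        assert back.categories == table.categories
        assert np.array_equal(back.counts, table.counts)
        assert back.denominator == 10


class TestPrevalenceRatio:
    @pytest.mark.parametrize("cat", sorted(COMPARISON_ROWS))
    def test_published_ratio_column(self, cat):
        trial, telegram, expected = COMPARISON_ROWS[cat]
        ratio = prevalence_ratio(telegram, TELEGRAM_N, trial, TRIAL_N)
        assert round(ratio, 2) == expected

    def test_equal_prevalences_give_unity(self):
        assert prevalence_ratio(5, 100, 10, 200) == pytest.approx(1.0)

    def test_reciprocal_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.integers(1, 50, 2)
            na, nb = rng.integers(50, 200, 2)
            fwd = prevalence_ratio(a, na, b, nb)
            rev = prevalence_ratio(b, nb, a, na)
            assert fwd * rev == pytest.approx(1.0)

    def test_zero_reference_gives_infinite_flag(self):
        assert math.isinf(prevalence_ratio(5, 10, 0, 10))


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    observed = table_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_prob(x)
        if p <= observed * (1 + 1e-9):
            total += p
    return total


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_diagonal_table_enumeration_value(self):
        # [[5,0],[0,5]]: only the two extreme tables are as improbable
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_on_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 9, 4))
        if a + b + c + d == 0:
            a = 1
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            _fisher_oracle(a, b, c, d), rel=1e-9
        )

    def test_transpose_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact_2x2(a, c, b, d)
            )

    def test_all_zero_table_convention(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


def _mw_oracle(x, y):
    """Two-sided Mann-Whitney p by direct pairwise-count enumeration.

    U is computed from pairwise wins (ties count half), independently of
    the midrank route used by the implementation.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2

    def u_of(idx):
        group1 = [pooled[i] for i in idx]
        group2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in group1 for b in group2
        )

    u_obs = u_of(tuple(range(n1)))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(set(idx)) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        comp = mann_whitney_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert comp.p_value == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, rng.integers(3, 8)).tolist()
        y = rng.integers(0, 5, rng.integers(3, 8)).tolist()
        comp = mann_whitney_compare(x, y)
        assert comp.method == "exact"
        assert comp.p_value == pytest.approx(_mw_oracle(x, y), rel=1e-9)

    def test_configured_gender_effect_is_significant(
        self, default_corpus_10k, ae_counts_10k
    ):
        _, _, recs = default_corpus_10k
        g = np.array([r.gender for r in recs])
        comp = mann_whitney_compare(
            ae_counts_10k[g == "female"], ae_counts_10k[g == "male"], "female", "male"
        )
        assert comp.p_value < 0.001
        assert comp.mean_a > comp.mean_b

    def test_descriptives_attached(self):
        comp = mann_whitney_compare([0, 1, 2, 2, 3], [0, 0, 1, 1], "a", "b")
        assert comp.quartiles_a[0] <= comp.quartiles_a[1] <= comp.quartiles_a[2]
        assert comp.ratio_of_means == pytest.approx(comp.mean_a / comp.mean_b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_compare([], [1, 2])


class TestShapiroWilk:
    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0] * 10)

    def test_gaussian_rejection_rate_calibrated(self):
        """Type-I error near the nominal 5% over repeated Gaussian samples."""
        rejections = 0
        runs = 1000
        for seed in range(runs):
            x = np.random.default_rng(seed).normal(size=100)
            _, p = shapiro_wilk(x)
            rejections += p < 0.05
        assert abs(rejections / runs - 0.05) < 0.02

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(0).exponential(size=500)
        _, p = shapiro_wilk(x)
        assert p < 0.001

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestAgeRegression:
    def test_noiseless_linear_counts_recovered_exactly(self):
        ages = np.arange(20, 80)
        counts = 5.0 - 0.04 * ages
        fit = fit_age_slope(ages, counts)
        assert fit.slope == pytest.approx(0.04, abs=1e-10)
        assert fit.direction == -1
        assert fit.slope_se == pytest.approx(0.0, abs=1e-10)

    def test_min_age_filter_applied(self):
        ages = np.array([10, 12, 30, 40, 50, 60])
        counts = np.array([99.0, 99.0, 4.0, 3.6, 3.2, 2.8])
        fit = fit_age_slope(ages, counts, min_age=18)
        assert fit.n == 4
        assert fit.slope == pytest.approx(0.04, abs=1e-10)

    def test_shuffled_counts_give_null_slope(self, default_corpus_10k, ae_counts_10k):
        _, _, recs = default_corpus_10k
        ages = np.array([r.age if r.age is not None else np.nan for r in recs])
        keep = ~np.isnan(ages)
        shuffled = np.random.default_rng(8).permutation(ae_counts_10k[keep])
        fit = fit_age_slope(ages[keep], shuffled)
        assert fit.slope < 2 * fit.slope_se

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_age_slope([30, 30, 30], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_age_slope([20, 30], [1, 2])


class TestCorrelation:
    def test_published_trial_comparison_correlation(self):
        trial = [6.70, 2.92, 3.01, 3.11, 1.17, 3.79, 0.78]
        telegram = [25.65, 12.90, 20.43, 23.62, 1.30, 2.17, 0.43]
        r, p = correlation(trial, telegram, "pearson")
        assert round(r, 2) == 0.69
        assert p == pytest.approx(0.09, abs=0.005)

    def test_published_registry_comparison_correlation(self):
        registry = [33.25, 38.10, 5.98, 9.34, 8.34]
        telegram = [54.70, 39.67, 5.14, 7.31, 9.53]
        r, p = correlation(registry, telegram, "pearson")
        assert round(r, 2) == 0.94
        assert p == pytest.approx(0.02, abs=0.005)

    def test_identity_gives_unit_correlation(self):
        x = [1.0, 2.0, 5.0, 9.0]
        for method in ("pearson", "spearman"):
            r, _ = correlation(x, x, method)
            assert r == pytest.approx(1.0)

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(30), rng.random(30)
        from scipy.stats import rankdata

        r_s, _ = correlation(x, y, "spearman")
        r_p, _ = correlation(rankdata(x), rankdata(y), "pearson")
        assert r_s == pytest.approx(r_p)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation([1, 1, 1], [1, 2, 3])


def test_p_value_display_convention():
    assert format_p(0.0004) == "<.001"
    assert format_p(0.049) == ".049"
    assert format_p(0.83) == ".830"
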