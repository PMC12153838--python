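"""Cohort statistics against independent brute-force oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rapscore import (
    FEATURE_CODES,
    FeatureMatrix,
    SideAggregation,
    cooccurrence,
    incidence_ratio,
    length_comparisons,
    overall_fisher,
    per_feature_tests,
    prevalence,
    significant_count,
    survival_compare,
)
from rapscore._stats import holm_adjust


def matrix_from_array(arr, ids=None, label=""):
    cols = [f"{c}_{s}" for c in FEATURE_CODES for s in ("L", "R")]
    df = pd.DataFrame(np.asarray(arr, dtype=float), columns=cols)
    if ids is not None:
        df.index = ids
    return FeatureMatrix(df, label=label)


def random_matrix(rng, n, p=0.3, missing=0.0):
    arr = (rng.random((n, 44)) < p).astype(float)
    if missing:
        arr[rng.random((n, 44)) < missing] = np.nan
    return matrix_from_array(arr)


class TestPrevalence:
    def test_all_ones_feature_has_prevalence_one(self):
        arr = np.zeros((6, 44))
        arr[:, 0] = 1.0  # R1 left
        arr[:, 1] = 1.0  # R1 right
        summary = prevalence(matrix_from_array(arr))
        assert summary.per_feature.loc["R1", "prevalence"] == 1.0
        assert summary.per_feature.loc["R2", "prevalence"] == 0.0

    def test_positive_fraction_matches_slot_counts(self):
        arr = np.zeros((50, 44))
        flat = arr.reshape(-1)
        flat[:989] = 1.0
        m = matrix_from_array(arr)
        assert m.slot_count == 2200
        assert 100.0 * m.positive_count / m.slot_count == pytest.approx(44.95, abs=0.01)

    @pytest.mark.parametrize("aggregation", list(SideAggregation))
    def test_matches_brute_force_column_means(self, rng, aggregation):
        for _ in range(20):
            m = random_matrix(rng, n=rng.integers(2, 30), p=rng.random(), missing=0.1)
            summary = prevalence(m, aggregation)
            for i, code in enumerate(FEATURE_CODES):
                block = m.df.iloc[:, [2 * i, 2 * i + 1]].to_numpy()
                if aggregation is SideAggregation.BY_SIDE:
                    units = block.reshape(-1)
                else:
                    units = np.array(
                        [np.nan if np.isnan(row).all() else np.nanmax(row) for row in block]
                    )
                n = np.sum(~np.isnan(units))
                k = np.nansum(units == 1.0)
                got = summary.per_feature.loc[code]
                assert got["n_units"] == n and got["n_positive"] == k

    def test_missing_entries_excluded_from_denominator(self):
        arr = np.zeros((4, 44))
        arr[0, 0] = 1.0
        arr[1, 0] = np.nan
        arr[1, 1] = np.nan
        summary = prevalence(matrix_from_array(arr), SideAggregation.ANY_SIDE)
        assert summary.per_feature.loc["R1", "n_units"] == 3
        assert summary.per_feature.loc["R1", "prevalence"] == pytest.approx(1 / 3)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            prevalence(matrix_from_array(np.zeros((0, 44))))


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    n1, n2, m1 = a + b, c + d, a + c
    total = n1 + n2
    denom = comb(total, m1)
    p_obs = Fraction(comb(n1, a) * comb(n2, m1 - a), denom)
    p = Fraction(0)
    for k in range(max(0, m1 - n2), min(n1, m1) + 1):
        pk = Fraction(comb(n1, k) * comb(n2, m1 - k), denom)
        if pk <= p_obs:
            p += pk
    return float(p)


class TestOverallFisher:
    def test_study_scale_counts_are_highly_discriminative(self):
        assert overall_fisher(16, 1056, 989, 2200) < 1e-4

    def test_identical_proportions_give_p_one(self):
        assert overall_fisher(5, 5, 5, 5) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            overall_fisher(6, 5, 1, 10)

    def test_matches_enumeration_oracle_on_small_tables(self):
        for n1 in range(1, 13):
            for n2 in range(1, 13):
                for a in range(0, n1 + 1, 2):
                    for c in range(0, n2 + 1, 3):
                        p = overall_fisher(a, n1, c, n2)
                        assert p == pytest.approx(
                            fisher_oracle(a, n1 - a, c, n2 - c), abs=1e-10
                        ), (a, n1, c, n2)


class TestPerFeatureTests:
    def test_chi_square_matches_hand_formula(self):
        # group x presence table: [[8, 16], [30, 20]]
        arr_m = np.zeros((24, 44))
        arr_m[:8, 0] = 1.0
        arr_a = np.zeros((50, 44))
        arr_a[:30, 0] = 1.0
        tests = per_feature_tests(matrix_from_array(arr_m), matrix_from_array(arr_a))
        # textbook Pearson statistic, computed by hand from the margins
        n = 74.0
        row = np.array([24.0, 50.0])
        col = np.array([38.0, 36.0])
        observed = np.array([[8.0, 16.0], [30.0, 20.0]])
        expected = np.outer(row, col) / n
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert tests.loc["R1", "chi2"] == pytest.approx(chi2, rel=1e-12)

    def test_equal_prevalence_is_not_significant(self):
        arr_m = np.zeros((40, 44))
        arr_m[:20, 2] = 1.0  # R2 left on half
        arr_a = np.zeros((40, 44))
        arr_a[:20, 2] = 1.0
        tests = per_feature_tests(matrix_from_array(arr_m), matrix_from_array(arr_a))
        assert tests.loc["R2", "p_value"] == pytest.approx(1.0)

    def test_zero_margin_reported_untestable_not_nan_p(self):
        tests = per_feature_tests(
            matrix_from_array(np.zeros((10, 44))), matrix_from_array(np.zeros((10, 44)))
        )
        assert not tests["testable"].any()
        assert significant_count(tests) == 0


class TestCooccurrence:
    def test_perfectly_correlated_features(self):
        arr = np.zeros((9, 44))
        arr[:4, 0] = arr[:4, 1] = 1.0  # R1 both sides
        arr[:4, 18] = 1.0  # P1 left (columns: 9 codes before P1 -> index 18)
        m = matrix_from_array(arr)
        cooc = cooccurrence(m, SideAggregation.ANY_SIDE)
        assert cooc.loc["R1", "R1"] == 4
        assert cooc.loc["R1", "P1"] == cooc.loc["P1", "P1"] == 4

    def test_matches_brute_force_and_count(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n=12, p=0.4, missing=0.05)
            for agg in SideAggregation:
                cooc = cooccurrence(m, agg)
                units = {
                    c: m.feature_units(c, agg).fillna(0.0).to_numpy() for c in FEATURE_CODES
                }
                for a in ("R1", "A3.1", "P2", "S5"):
                    for b in ("R2", "P1", "S6"):
                        expected = int(np.sum((units[a] == 1) & (units[b] == 1)))
                        assert cooc.loc[a, b] == expected
                        assert cooc.loc[b, a] == expected

    def test_pair_counts_bounded_by_diagonal(self, rng):
        m = random_matrix(rng, n=25, p=0.5)
        cooc = cooccurrence(m)
        diag = np.diag(cooc.to_numpy())
        assert (cooc.to_numpy() <= np.minimum.outer(diag, diag)).all()

    def test_independent_features_near_product_rate(self, rng):
        n = 4000
        arr = np.zeros((n, 44))
        arr[:, 0] = rng.random(n) < 0.5  # R1 left
        arr[:, 18] = rng.random(n) < 0.4  # P1 left
        cooc = cooccurrence(matrix_from_array(arr), SideAggregation.BY_SIDE)
        expected = n * 0.5 * 0.4
        se = np.sqrt(n * 0.2 * 0.8)
        assert abs(cooc.loc["R1", "P1"] - expected) < 4 * se

    def test_bilateral_once_counts_mirrored_features_once(self):
        arr = np.zeros((5, 44))
        a2 = 2 * FEATURE_CODES.index("A2")
        arr[:, a2] = arr[:, a2 + 1] = 1.0
        m = matrix_from_array(arr)
        assert cooccurrence(m, SideAggregation.BY_SIDE).loc["A2", "A2"] == 10
        assert (
            cooccurrence(m, SideAggregation.BY_SIDE, bilateral_once=True).loc["A2", "A2"] == 5
        )


def holm_oracle(pvals):
    """Textbook Holm step-down, written independently of the implementation."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


class TestHolm:
    def test_identical_raw_ps_scale_by_family_size(self):
        assert holm_adjust([0.01] * 5)[0] == pytest.approx(0.05)

    @given(
        pvals=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
    )
    def test_never_decreases_and_monotone(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @settings(max_examples=200)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 15))
    def test_matches_brute_force_oracle(self, seed, m):
        pvals = np.random.default_rng(seed).random(m).tolist()
        assert holm_adjust(pvals) == pytest.approx(holm_oracle(pvals), abs=1e-12)

    @given(seed=st.integers(0, 1000))
    def test_permutation_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        pvals = rng.random(8)
        perm = rng.permutation(8)
        assert holm_adjust(pvals[perm]) == pytest.approx(holm_adjust(pvals)[perm])


class TestLengthComparisons:
    def test_pairwise_family_with_holm(self, rng):
        groups = {
            "a": rng.normal(10, 1, 30),
            "b": rng.normal(10, 1, 30),
            "c": rng.normal(14, 1, 30),
        }
        table = length_comparisons(groups)
        assert len(table) == 3
        assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_holm"] <= 1.0).all()
        sig = table[(table["group_a"] == "a") & (table["group_b"] == "c")]
        assert float(sig["p_holm"].iloc[0]) < 0.01

    def test_singleton_family_unadjusted(self, rng):
        table = length_comparisons({"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)})
        assert table["p_holm"].iloc[0] == pytest.approx(table["p_raw"].iloc[0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            length_comparisons({"a": [1.0], "b": []})


class TestSurvival:
    def test_identical_groups_log_rank_null(self):
        ages = [3.0, 5.0, 7.0, 9.0, 11.0]
        res = survival_compare(ages, list(ages))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_km_curve_properties(self):
        res = survival_compare([2.0, 4.0, 4.0, 8.0], [3.0, 5.0], labels=("x", "y"))
        curve = res.km_curves["x"]
        surv = curve["survival"].to_numpy()
        assert surv[0] == 1.0
        assert np.all(np.diff(surv) <= 1e-12)  # non-increasing step function
        assert surv[-1] == pytest.approx(0.0)  # no censoring: drops to zero

    def test_all_censored_group_rejected(self):
        with pytest.raises(ValueError):
            survival_compare([5.0, 6.0], [5.0, 6.0], events_b=[0, 0])

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            survival_compare([0.0, 5.0], [4.0])


class TestIncidenceRatio:
    def test_study_counts_give_tenfold_dd_cc(self):
        table = incidence_ratio({"DD": 50, "CC": 5, "CE": 3}, reference="CC")
        assert table.loc["DD", "raw_ratio"] == pytest.approx(10.0)
        assert table.loc["CE", "raw_ratio"] == pytest.approx(0.6)

    def test_equal_counts_and_densities_give_unit_ratios(self):
        table = incidence_ratio(
            {"DD": 4, "CC": 4}, densities={"DD": 2.0, "CC": 2.0}, reference="CC"
        )
        assert table["raw_ratio"].tolist() == [1.0, 1.0]
        assert table["adjusted_ratio"].tolist() == [1.0, 1.0]

    def test_equal_densities_leave_raw_ratio(self):
        table = incidence_ratio(
            {"DD": 50, "CC": 5}, densities={"DD": 3.0, "CC": 3.0}, reference="CC"
        )
        assert table.loc["DD", "adjusted_ratio"] == pytest.approx(
            table.loc["DD", "raw_ratio"]
        )

    def test_density_adjustment(self):
        table = incidence_ratio(
            {"DD": 50, "CC": 5}, densities={"DD": 5.0, "CC": 17.0}, reference="CC"
        )
        assert table.loc["DD", "adjusted_ratio"] == pytest.approx((50 / 5.0) / (5 / 17.0))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            incidence_ratio({"DD": 50, "CC": 0}, reference="CC")
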