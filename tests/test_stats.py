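"""Unit and property tests for the statistical core."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fusionnominate.stats import (
    DetectionContingency,
    bh_qvalues,
    breakpoint_rpkm,
    cluster_profiles,
    fisher_enrichment,
    fisher_enrichment_exact,
    format_pvalue,
    normalize_differential,
    paired_overexpression_test,
    unpaired_overexpression_test,
)


def brute_force_fisher_greater(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins."""
    n, k_pos, n_tum = a + b + c + d, a + c, a + b
    probs = {}
    for k in range(max(0, k_pos - (n - n_tum)), min(k_pos, n_tum) + 1):
        probs[k] = Fraction(
            math.factorial(k_pos) * math.factorial(n - k_pos)
            * math.factorial(n_tum) * math.factorial(n - n_tum),
            math.factorial(k) * math.factorial(k_pos - k)
            * math.factorial(n_tum - k) * math.factorial(n - k_pos - n_tum + k)
            * math.factorial(n),
        )
    return float(sum(p for k, p in probs.items() if k >= a))


class TestFisherEnrichment:
    @pytest.mark.parametrize(
        "a,c,printed",
        [
            (27, 1, "4.2E-10"),  # strongly tumor-enriched, nearly absent in benign
            (6, 0, "1.3E-02"),   # rare but tumor-exclusive
            (14, 2, "8.2E-04"),
            (25, 6, "2.0E-05"),
        ],
    )
    def test_reference_tables(self, a, c, printed):
        p = fisher_enrichment(DetectionContingency(a, 44 - a, c, 44 - c))
        assert format_pvalue(p) == printed

    def test_no_positives_gives_one(self):
        assert fisher_enrichment(DetectionContingency(0, 44, 0, 44)) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 21, size=2)
            a, c = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            ours = fisher_enrichment(DetectionContingency(a, n1 - a, c, n2 - c))
            oracle = brute_force_fisher_greater(a, n1 - a, c, n2 - c)
            assert ours == pytest.approx(oracle, rel=1e-12)

    def test_matches_scipy(self):
        for a in range(0, 45, 4):
            for c in range(0, 45, 4):
                ours = fisher_enrichment(DetectionContingency(a, 44 - a, c, 44 - c))
                ref = sps.fisher_exact([[a, 44 - a], [c, 44 - c]],
                                       alternative="greater")[1]
                assert ours == pytest.approx(ref, rel=1e-9)

    @given(st.integers(0, 19), st.integers(0, 20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_tumor_positives(self, a, c):
        """With the benign column fixed, more tumor positives never raises p."""
        p_lo = fisher_enrichment(DetectionContingency(a, 20 - a, c, 20 - c))
        p_hi = fisher_enrichment(DetectionContingency(a + 1, 19 - a, c, 20 - c))
        assert p_hi <= p_lo + 1e-15

    @given(st.integers(0, 15), st.integers(0, 15))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_tail_identity(self, a, c):
        """Upper and lower hypergeometric tails overlap exactly in the observed table."""
        ct = DetectionContingency(a, 15 - a, c, 15 - c)
        swapped = DetectionContingency(c, 15 - c, a, 15 - a)
        p_greater = fisher_enrichment_exact(ct)
        p_less_via_swap = fisher_enrichment_exact(swapped)
        n, k_pos = 30, a + c
        p_obs = Fraction(math.comb(k_pos, a) * math.comb(n - k_pos, 15 - a),
                         math.comb(n, 15))
        assert p_greater + p_less_via_swap - p_obs == 1

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            DetectionContingency(-1, 2, 3, 4)


class TestPairedSignedRank:
    def test_identical_vectors_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            assert paired_overexpression_test([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_all_positive_shift_closed_form(self):
        t = np.arange(1.0, 11.0)
        assert paired_overexpression_test(t + 1, t) == pytest.approx(1 / 2**10)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_sign_enumeration(self, trial):
        """Exact DP null equals brute-force enumeration of all 2^n sign vectors."""
        rng = np.random.default_rng(100 + trial)
        n = 8
        d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding induces ties
        d = np.where(d == 0, 0.1, d)
        p_ours = paired_overexpression_test(d, np.zeros(n))
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = 0
        for signs in range(2**n):
            w = sum(r for i, r in enumerate(ranks) if (signs >> i) & 1)
            count += w >= w_obs - 1e-9
        assert p_ours == pytest.approx(count / 2**n, abs=1e-12)

    def test_large_n_close_to_scipy_approximation(self):
        rng = np.random.default_rng(5)
        t = rng.normal(1.0, 1.0, 60)
        b = rng.normal(0.0, 1.0, 60)
        ours = paired_overexpression_test(t, b)
        ref = sps.wilcoxon(t, b, alternative="greater", correction=True,
                           method="approx").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            paired_overexpression_test([1.0, 2.0], [1.0])


class TestUnpairedRankSum:
    def test_complete_separation_closed_form(self):
        a, b = [6.0, 7, 8, 9, 10], [1.0, 2, 3, 4, 5]
        assert unpaired_overexpression_test(a, b) == pytest.approx(1 / math.comb(10, 5))

    def test_all_tied_is_half(self):
        assert unpaired_overexpression_test([2.0, 3, 4], [2.0, 3, 4]) == pytest.approx(
            0.5, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            unpaired_overexpression_test([], [1.0])


class TestBreakpointRpkm:
    def test_unit_case(self):
        assert breakpoint_rpkm(10, 1000, 10**7) == pytest.approx(1.0)

    def test_zero_reads(self):
        assert breakpoint_rpkm(0, 200, 10**7) == 0.0

    def test_linear_in_split_reads(self):
        base = breakpoint_rpkm(7, 200, 44_000_000)
        assert breakpoint_rpkm(14, 200, 44_000_000) == pytest.approx(2 * base)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            breakpoint_rpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            breakpoint_rpkm(1, 200, 0)


class TestNormalizeDifferential:
    def test_direct_formula(self):
        out = normalize_differential(np.array([2.0, -1.0, 4.0]), np.zeros(3))
        assert out == pytest.approx([0.5, -0.25, 1.0])

    def test_equal_matrices_map_to_zero(self):
        t = np.arange(12.0).reshape(3, 4)
        assert not normalize_differential(t, t).any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_row_max_abs_is_zero_or_one(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.gamma(2.0, 1.0, size=(5, 7))
        n = rng.gamma(2.0, 1.0, size=(5, 7))
        if rng.random() < 0.2:
            n[0] = t[0]  # force an all-zero difference row
        out = normalize_differential(t, n)
        row_max = np.abs(out).max(axis=1)
        assert np.all((row_max == 0) | np.isclose(row_max, 1.0))
        assert np.all(np.sign(out) == np.sign(t - n))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            normalize_differential(np.array([np.nan]), np.array([0.0]))


class TestClusterProfiles:
    def test_identical_rows_merge_at_zero(self):
        m = np.array([[1.0, 2, 3], [1.0, 2, 3], [3.0, 1, 2]])
        z, _, _ = cluster_profiles(m)
        assert z[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_at_distance_two(self):
        row = np.array([0.3, -0.8, 1.0, 0.1])
        z, _, _ = cluster_profiles(np.vstack([row, -row]))
        assert z[0][2] == pytest.approx(2.0)

    def test_three_row_distances_match_hand_computation(self):
        m = np.array([[1.0, 2.0, 4.0], [2.0, 2.5, 3.0], [5.0, 1.0, 0.0]])
        dists = {
            (i, j): 1 - sps.pearsonr(m[i], m[j])[0]
            for i, j in combinations(range(3), 2)
        }
        z, order, ids = cluster_profiles(m, ["a", "b", "c"])
        # first merge joins the closest pair at exactly its Pearson distance
        (i, j), dmin = min(dists.items(), key=lambda kv: kv[1])
        assert z[0][2] == pytest.approx(dmin, abs=1e-12)
        assert sorted(z[0][:2]) == [i, j]
        assert len(order) == 3 and ids == ["a", "b", "c"]

    def test_zero_variance_row_excluded_with_warning(self):
        m = np.array([[1.0, 1.0, 1.0], [1.0, 2, 3], [3.0, 2, 1]])
        with pytest.warns(UserWarning, match="zero-variance"):
            _, _, kept = cluster_profiles(m, ["flat", "up", "down"])
        assert kept == ["up", "down"]


class TestFormatting:
    @pytest.mark.parametrize("p,text", [
        (2.0053e-5, "2.0E-05"),
        (4.19e-10, "4.2E-10"),
        (1.0, "1.0E+00"),
        (None, "*"),
    ])
    def test_two_significant_figures(self, p, text):
        assert format_pvalue(p) == text

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            format_pvalue(1.5)

    def test_bh_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.04, 0.2, 0.9]
        q = bh_qvalues(p)
        assert np.all(q >= p) and np.all(q <= 1.0)
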