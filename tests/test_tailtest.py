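"""Equal-occupancy binning and the distribution tail test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cofunc.tailtest import (
    BinThresholds,
    bin_count_prefixes,
    bin_counts,
    distribution_tail_test,
    integer_thresholds,
    lexicographic_extreme,
    permutation_tail_test,
    quantile_thresholds,
)


class TestQuantileThresholds:
    def test_one_to_twenty_with_four_bins(self):
        thr = quantile_thresholds(np.arange(1, 21), 4)
        assert thr.thresholds == (0.0, 5.75, 10.5, 15.25, 20.0)
        assert list(bin_counts(np.arange(1, 21), thr)) == [5, 5, 5, 5]

    def test_single_bin(self):
        thr = quantile_thresholds([1.0, 2.0, 3.0], 1)
        assert thr.k == 1
        assert bin_counts([1.0, 2.0, 3.0], thr)[0] == 3

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="at least"):
            quantile_thresholds([1.0, 2.0], 5)

    def test_massive_ties_error_names_quantiles(self):
        with pytest.raises(ValueError, match="%"):
            quantile_thresholds([1.0] * 30, 4)

    def test_real_values_occupy_bins_uniformly(self):
        rng = np.random.default_rng(0)
        values = rng.exponential(size=300)
        thr = quantile_thresholds(values, 20)
        counts = bin_counts(values, thr)
        assert counts.sum() == 300  # no overflow for the defining values
        assert np.all(np.abs(counts - 15) <= 1)


class TestBinCounting:
    def test_everything_in_first_bin(self):
        thr = BinThresholds((0.0, 10.0, 20.0, 30.0))
        F = bin_count_prefixes(np.full(7, 5.0), thr)
        assert list(F) == [7, 7, 7]

    def test_empty_values(self):
        thr = BinThresholds((0.0, 1.0, 2.0))
        assert list(bin_count_prefixes([], thr)) == [0, 0]

    def test_overflow_excluded(self):
        thr = BinThresholds((0.0, 1.0, 2.0))
        assert list(bin_counts([0.5, 1.5, 99.0], thr)) == [1, 1]

    def test_boundary_values_go_left_bin(self):
        thr = BinThresholds((0.0, 1.0, 2.0))
        # bins are (t0, t1], (t1, t2]: exact threshold belongs to lower bin
        assert list(bin_counts([1.0, 2.0], thr)) == [1, 1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 100, allow_nan=False), min_size=0, max_size=50)
    )
    def test_prefixes_match_naive_comparison_count(self, values):
        thr = BinThresholds((0.0, 10.0, 25.0, 50.0, 100.0))
        F = bin_count_prefixes(values, thr)
        for j, t in enumerate(thr.thresholds[1:]):
            assert F[j] == sum(1 for v in values if v <= t)

    def test_integer_thresholds_bin_counts_exactly(self):
        thr = integer_thresholds(4)
        assert list(bin_counts([1, 1, 2, 4], thr)) == [2, 1, 0, 1]


class TestLexicographicOrder:
    def test_tie_then_exceed_is_extreme(self):
        assert lexicographic_extreme(
            np.array([5, 8, 1]), np.array([[5, 9, 0]])
        )[0]

    def test_below_first_coordinate_never_extreme(self):
        assert not lexicographic_extreme(
            np.array([5, 8, 1]), np.array([[4, 99, 99]])
        )[0]

    def test_equal_vector_is_extreme(self):
        assert lexicographic_extreme(np.array([3, 3]), np.array([[3, 3]]))[0]

    def test_matches_tuple_comparison_oracle(self):
        rng = np.random.default_rng(1)
        real = rng.integers(0, 5, size=6)
        reps = rng.integers(0, 5, size=(100, 6))
        got = lexicographic_extreme(real, reps)
        want = np.array([tuple(r) >= tuple(real) for r in reps])
        assert np.array_equal(got, want)


class TestDistributionTailTest:
    def test_forced_first_bin_enrichment(self):
        """All real values in bin 1, replicates spread out -> j*=1, p=0.001."""
        rng = np.random.default_rng(2)
        real = rng.uniform(0, 1, size=100)
        thr = BinThresholds(tuple(np.arange(0.0, 21.0)))  # bins (0,1], (1,2], ...
        reps = [rng.uniform(0, 20, size=100) for _ in range(999)]
        res = distribution_tail_test(real, reps, thresholds=thr, alpha=0.05)
        assert res.j_star == 1
        assert res.p_corrected == pytest.approx(0.001)
        assert res.p_values[0] == pytest.approx(1 / 1000)

    def test_alpha_zero_never_significant(self):
        rng = np.random.default_rng(3)
        real = rng.uniform(size=50)
        reps = [rng.uniform(size=50) for _ in range(99)]
        res = distribution_tail_test(real, reps, k=5, alpha=0.0)
        assert res.j_star is None and res.p_corrected is None

    def test_minimal_j_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            k, n = 8, 60
            F_real = np.sort(rng.integers(0, 30, size=k))
            F_reps = np.sort(rng.integers(0, 30, size=(n, k)), axis=1)
            p = (np.sum(F_reps >= F_real, axis=0) + 1) / (n + 1)
            j_star = None
            for j in range(1, k + 1):
                if j * p[j - 1] <= 0.2:
                    j_star = j
                    break
            from cofunc.tailtest import _tail_from_prefixes

            res = _tail_from_prefixes(
                BinThresholds(tuple(range(k + 1))), F_real, F_reps, alpha=0.2
            )
            assert res.j_star == j_star
            if j_star is not None:
                assert res.p_corrected == pytest.approx(min(1.0, j_star * p[j_star - 1]))
                assert res.p_corrected >= res.p_values[j_star - 1]

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(5)
        real = rng.uniform(0, 0.4, size=60)
        reps = [rng.uniform(0, 1, size=60) for _ in range(199)]
        res_tight = distribution_tail_test(real, reps, k=5, alpha=0.01)
        res_loose = distribution_tail_test(real, reps, k=5, alpha=0.2)
        if res_tight.j_star is not None:
            assert res_loose.j_star is not None
            assert res_loose.j_star <= res_tight.j_star

    def test_p_floor(self):
        rng = np.random.default_rng(6)
        real = rng.uniform(size=40)
        reps = [rng.uniform(size=40) for _ in range(49)]
        res = distribution_tail_test(real, reps, k=4)
        assert np.all(res.p_values >= 1 / 50)

    def test_null_false_positive_rate_bounded(self):
        """Replicates from the real distribution: familywise error <= alpha."""
        rng = np.random.default_rng(7)
        hits = 0
        reps_count = 150
        for _ in range(reps_count):
            real = rng.uniform(size=60)
            reps = rng.uniform(size=(99, 60))
            res = distribution_tail_test(real, list(reps), k=10, alpha=0.05)
            hits += res.j_star is not None
        # Bonferroni-by-j keeps FWER <= alpha; allow 3 binomial SEs of slack
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps_count)
        assert hits / reps_count <= bound


class TestPermutationTailTest:
    def test_chromosome_counts_use_integer_bins(self, small_study):
        _, layout, collection, _ = small_study
        res = permutation_tail_test(
            layout, collection, "chrom_counts", scheme="global", n=99, seed=0
        )
        assert res.thresholds.k == 3  # one bin per chromosome
        assert res.prefixes_real[-1] == len(collection)

    def test_reproducible_and_refinable(self, small_study):
        _, layout, collection, _ = small_study
        kwargs = dict(
            values="linear_group_means", scheme="within_chromosome",
            n=49, k=5, seed=3, refinement="lexicographic",
        )
        r1 = permutation_tail_test(layout, collection, **kwargs)
        r2 = permutation_tail_test(layout, collection, **kwargs)
        assert np.array_equal(r1.prefixes_replicates, r2.prefixes_replicates)
        assert r1.p_lexicographic == r2.p_lexicographic
        assert 0 < r1.p_lexicographic <= 1
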