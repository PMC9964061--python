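"""Per-marker statistics, smoothing, thresholding and peak location."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact

from bsamap import (
    DataError,
    SmoothedTrack,
    allele_frequency,
    bonferroni_threshold,
    candidate_interval,
    chisq_2x2,
    fisher_two_tailed,
    fisher_two_tailed_many,
    locate_peak,
    moving_average,
    weighted_geomean_p,
)


def fisher_oracle(a, b, c, d):
    """Exact two-tailed Fisher p by integer-arithmetic enumeration.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is <= the observed one; the comparison is
    on exact integer numerators (shared denominator), so no floating
    point enters until the final division.
    """
    n1, n2, k = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or k == 0 or k == n1 + n2:
        return 1.0
    lo, hi = max(0, k - n2), min(n1, k)
    nums = {x: math.comb(n1, x) * math.comb(n2, k - x) for x in range(lo, hi + 1)}
    denom = math.comb(n1 + n2, k)
    obs = nums[a]
    return sum(v for v in nums.values() if v <= obs) / denom


class TestAlleleFrequency:
    @pytest.mark.parametrize("a, b, f", [(0, 50, 0.0), (25, 75, 0.25), (40, 0, 1.0)])
    def test_fraction(self, a, b, f):
        assert allele_frequency(a, b) == f

    def test_zero_depth_is_an_error(self):
        with pytest.raises(DataError):
            allele_frequency(0, 0)


class TestFisherTwoTailed:
    def test_identical_pools_give_one(self):
        assert fisher_two_tailed(10, 10, 10, 10) == 1.0

    def test_fully_discordant_5x5(self):
        # margins (5,5;5,5): only a=5 and a=0 are as extreme, each 1/252
        assert fisher_two_tailed(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-12)

    def test_small_table_matches_enumeration(self):
        assert fisher_two_tailed(3, 1, 1, 3) == pytest.approx(
            fisher_oracle(3, 1, 1, 3), rel=1e-12
        )
        assert fisher_oracle(3, 1, 1, 3) == 34 / 70

    def test_zero_margin_returns_one(self):
        assert fisher_two_tailed(0, 0, 5, 5) == 1.0
        assert fisher_two_tailed(0, 3, 0, 5) == 1.0

    @given(
        a=st.integers(0, 40), b=st.integers(0, 40),
        c=st.integers(0, 40), d=st.integers(0, 40),
    )
    def test_invariant_under_row_and_column_swap(self, a, b, c, d):
        p = fisher_two_tailed(a, b, c, d)
        assert fisher_two_tailed(c, d, a, b) == pytest.approx(p, rel=1e-9)
        assert fisher_two_tailed(b, a, d, c) == pytest.approx(p, rel=1e-9)

    @given(
        a=st.integers(0, 60), b=st.integers(0, 60),
        c=st.integers(0, 60), d=st.integers(0, 60),
    )
    def test_matches_scipy_reference(self, a, b, c, d):
        """scipy's fisher_exact (the established implementation) agrees."""
        ours = fisher_two_tailed(a, b, c, d)
        ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(7)
        tables = rng.integers(0, 100, size=(300, 4))
        many = fisher_two_tailed_many(*tables.T)
        for row, p in zip(tables, many):
            assert p == pytest.approx(fisher_two_tailed(*row), rel=1e-10)


class TestChisq2x2:
    def test_no_association(self):
        stat, p = chisq_2x2(10, 10, 10, 10)
        assert stat == 0.0 and p == 1.0

    def test_statistic_equals_cellwise_formula(self):
        a, b, c, d = 30, 10, 10, 30
        n = a + b + c + d
        exp = [
            (a + b) * (a + c) / n, (a + b) * (b + d) / n,
            (c + d) * (a + c) / n, (c + d) * (b + d) / n,
        ]
        brute = sum((o - e) ** 2 / e for o, e in zip((a, b, c, d), exp))
        assert chisq_2x2(a, b, c, d)[0] == pytest.approx(brute, rel=1e-12)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(DataError):
            chisq_2x2(0, 0, 5, 5)

    def test_asymptotic_agreement_with_fisher(self):
        """At pool-seq depths the chi-square p is within a factor of 2 of
        the exact Fisher p for non-extreme tables (total >= 200)."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            depths = rng.integers(100, 160, size=2)
            a = rng.binomial(depths[0], 0.5)
            c = rng.binomial(depths[1], 0.5)
            table = (a, depths[0] - a, c, depths[1] - c)
            p_f = fisher_two_tailed(*table)
            if not (0.01 <= p_f <= 0.99):
                continue
            p_c = chisq_2x2(*table)[1]
            assert p_c / p_f < 2 and p_f / p_c < 2, table
            checked += 1


class TestMovingAverage:
    def test_constant_series_is_identity_on_values(self):
        pos = np.arange(1, 21)
        sm = moving_average(pos, np.full(20, 0.4), window=7)
        assert np.allclose(sm.value, 0.4)

    def test_pairwise_means(self):
        sm = moving_average(np.array([10, 20, 30, 40]), np.array([0, 1, 0, 1]), 2)
        assert list(sm.value) == [0.5, 0.5, 0.5]
        assert list(sm.anchor_pos) == [10, 20, 30]  # anchored at ceil(k/2)-th member

    def test_window_one_is_identity(self):
        pos = np.array([5, 9, 14])
        vals = np.array([0.1, 0.9, 0.3])
        sm = moving_average(pos, vals, 1)
        assert list(sm.anchor_pos) == [5, 9, 14]
        assert np.allclose(sm.value, vals)

    def test_short_track_yields_empty_with_room_for_none(self):
        sm = moving_average(np.array([1, 2]), np.array([0.5, 0.5]), window=5)
        assert len(sm) == 0

    @given(seed=st.integers(0, 10_000), k=st.integers(1, 15))
    def test_values_bounded_by_window_inputs(self, seed, k):
        rng = np.random.default_rng(seed)
        n = 30
        vals = rng.random(n)
        sm = moving_average(np.arange(1, n + 1), vals, k)
        for i, v in enumerate(sm.value):
            window = vals[i : i + k]
            assert window.min() - 1e-12 <= v <= window.max() + 1e-12


class TestWeightedGeomeanP:
    def test_equal_p_is_idempotent(self):
        pos = np.arange(1, 11)
        sm = weighted_geomean_p(pos, np.full(10, 0.2), np.full(10, 50.0), 4)
        assert np.allclose(sm.value, 0.2)

    def test_two_marker_window_value(self):
        # exp((10*ln 0.1 + 30*ln 0.001)/40) = 10^-2.5
        sm = weighted_geomean_p(
            np.array([1, 2]), np.array([0.1, 0.001]), np.array([10.0, 30.0]), 2
        )
        assert sm.value[0] == pytest.approx(10 ** -2.5, rel=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_equal_weights_reduce_to_unweighted_geomean(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(20) * 0.99 + 1e-6
        k = 5
        sm = weighted_geomean_p(np.arange(1, 21), p, np.full(20, 7.0), k)
        for i, v in enumerate(sm.value):
            expected = np.exp(np.mean(np.log(p[i : i + k])))
            assert v == pytest.approx(expected, rel=1e-12)

    def test_zero_weight_window_falls_back_to_unweighted(self):
        p = np.array([0.1, 0.4, 0.9])
        sm = weighted_geomean_p(np.array([1, 2, 3]), p, np.zeros(3), 3)
        assert sm.value[0] == pytest.approx(np.exp(np.mean(np.log(p))))

    def test_tiny_p_values_stay_finite(self):
        p = np.array([0.0, 1e-310, 0.5, 0.5])
        sm = weighted_geomean_p(np.array([1, 2, 3, 4]), p, np.full(4, 10.0), 2)
        assert np.all(np.isfinite(sm.value)) and np.all(sm.value > 0)


class TestBonferroni:
    def test_values(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)
        assert bonferroni_threshold(0.05, 237_774) == pytest.approx(0.05 / 237_774)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def smoothed(values, positions=None, chrom="chr2"):
    values = np.asarray(values, dtype=float)
    pos = np.asarray(positions if positions is not None else np.arange(1, values.size + 1))
    return SmoothedTrack(chrom, 1, pos, values)


class TestLocatePeak:
    def test_unique_maximum(self):
        assert locate_peak(smoothed([0.1, 0.9, 0.2], [1000, 5000, 9000])) == 5000

    def test_tie_broken_by_smallest_position(self):
        assert locate_peak(smoothed([0.9, 0.9], [1000, 2000])) == 1000

    def test_monotone_track_peaks_at_last_anchor(self):
        assert locate_peak(smoothed([0.1, 0.2, 0.3], [10, 20, 30])) == 30

    def test_min_mode(self):
        assert locate_peak(smoothed([0.5, 0.01, 0.3], [10, 20, 30]), mode="min") == 20

    def test_empty_track_is_an_error(self):
        with pytest.raises(DataError):
            locate_peak(smoothed([]))


class TestCandidateInterval:
    def test_single_subthreshold_anchor(self):
        sm = smoothed([0.5, 1e-9, 0.5], [1_100_000, 1_200_000, 1_300_000])
        iv = candidate_interval(sm, threshold=1e-6, pad_bp=100_000)
        assert (iv.start_pos, iv.end_pos) == (1_100_000, 1_300_000)
        assert iv.anchor == 1_200_000 and iv.sub_threshold

    def test_fallback_when_nothing_subthreshold(self):
        sm = smoothed([0.5, 0.01, 0.5], [400_000, 500_000, 600_000])
        iv = candidate_interval(sm, threshold=1e-6, pad_bp=100_000)
        assert (iv.start_pos, iv.end_pos) == (400_000, 600_000)
        assert not iv.sub_threshold

    def test_run_of_subthreshold_anchors_extended_by_pad(self):
        pos = [1_050_000, 1_100_000, 1_200_000, 1_300_000, 1_350_000, 1_400_000]
        vals = [0.5, 1e-7, 1e-9, 1e-8, 1e-7, 0.5]
        iv = candidate_interval(smoothed(vals, pos), threshold=1e-6, pad_bp=100_000)
        assert (iv.start_pos, iv.end_pos) == (1_000_000, 1_450_000)

    def test_clipped_to_chromosome_span(self):
        sm = smoothed([1e-9], [50_000])
        iv = candidate_interval(sm, 1e-6, pad_bp=100_000, span=(10_000, 120_000))
        assert (iv.start_pos, iv.end_pos) == (10_000, 120_000)
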