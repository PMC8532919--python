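"""Roaming entropy: contact tallies, RE, cRE and summaries.

The high-precision fixture log(2)/log(27) = 0.21030991785715247 was computed
directly from the definition with exact arithmetic.
"""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from roamkit.entropy import (
    ContactDistribution,
    RoamingSeries,
    contact_distribution,
    cumulative_re,
    group_summary,
    roaming_entropy,
    variance_trajectory,
)

from .conftest import make_log

K = 27


def dist(counts, k=K):
    c = np.zeros(k, dtype=int)
    for a, n in counts.items():
        c[a - 1] = n
    return ContactDistribution("M01", "n", c, k)


class TestContactDistribution:
    def test_direct_tally(self, tiny_night_log):
        d = contact_distribution(tiny_night_log, "M01", K)
        assert d.counts[4] == 2 and d.counts[6] == 1
        assert d.p[4] == pytest.approx(2 / 3)
        assert d.p[6] == pytest.approx(1 / 3)

    def test_absent_animal_is_empty_flagged(self, tiny_night_log):
        d = contact_distribution(tiny_night_log, "M99", K)
        assert d.empty and d.total == 0

    def test_uniform_over_all_antennas(self):
        rows = [(f"2019-06-01T21:{m:02d}:00", a, "M01") for m, a in enumerate(range(1, 28))]
        d = contact_distribution(make_log(rows), "M01", K)
        assert np.allclose(d.p, 1 / 27)

    def test_k_below_layout_rejected(self, tiny_night_log):
        with pytest.raises(ValueError, match="smaller than layout"):
            contact_distribution(tiny_night_log, "M01", 10)


class TestRoamingEntropy:
    def test_uniform_is_exactly_one(self):
        assert roaming_entropy(np.full(K, 1 / K), K) == 1.0

    def test_one_hot_is_exactly_zero(self):
        for j in range(K):
            p = np.zeros(K)
            p[j] = 1.0
            assert roaming_entropy(p, K) == 0.0

    def test_two_antenna_split_matches_closed_form(self):
        p = np.zeros(K)
        p[0] = p[1] = 0.5
        assert roaming_entropy(p, K) == pytest.approx(0.21030991785715247, abs=1e-12)

    def test_empty_distribution_is_missing(self):
        assert np.isnan(roaming_entropy(dist({})))

    def test_k_of_one_rejected(self):
        with pytest.raises(ValueError, match="k must exceed 1"):
            roaming_entropy(dist({1: 3}, k=1))

    def test_matches_scipy_entropy(self):
        # independent route: scipy's Shannon entropy with explicit base k
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.dirichlet(np.ones(K))
            expected = scipy.stats.entropy(p) / np.log(K)
            assert roaming_entropy(p, K) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 1000), min_size=K, max_size=K).filter(lambda c: sum(c) > 0))
    def test_bounds_hold_for_any_counts(self, counts):
        d = ContactDistribution("M", "n", np.array(counts), K)
        re = roaming_entropy(d)
        assert 0.0 <= re <= 1.0

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(1, 500), min_size=2, max_size=K),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, counts, rnd):
        c = np.zeros(K, dtype=int)
        c[: len(counts)] = counts
        perm = list(range(K))
        rnd.shuffle(perm)
        re1 = roaming_entropy(ContactDistribution("M", "n", c, K))
        re2 = roaming_entropy(ContactDistribution("M", "n", c[perm], K))
        assert re1 == pytest.approx(re2, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(1, 500), min_size=3, max_size=K))
    def test_merging_antennas_never_increases_re(self, counts):
        c = np.zeros(K, dtype=int)
        c[: len(counts)] = counts
        merged = c.copy()
        merged[0] += merged[1]
        merged[1] = 0
        assert roaming_entropy(ContactDistribution("M", "n", merged, K)) <= roaming_entropy(
            ContactDistribution("M", "n", c, K)
        ) + 1e-12


class TestCumulativeRe:
    def test_running_sum(self):
        assert np.allclose(cumulative_re([0.5, 0.3]), [0.5, 0.8])

    def test_empty_series(self):
        assert cumulative_re([]).size == 0

    def test_constant_series_arithmetic(self):
        # 136 nights at RE 0.06 accumulate to 8.16
        cre = cumulative_re(np.full(136, 0.06))
        assert cre[-1] == pytest.approx(8.16, abs=1e-9)

    def test_missing_nights_contribute_zero(self):
        cre = cumulative_re([0.5, np.nan, 0.3])
        assert np.allclose(cre, [0.5, 0.5, 0.8])

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            cumulative_re([0.5], missing_policy="interpolate")

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.one_of(st.floats(0, 1), st.just(float("nan"))), max_size=50))
    def test_non_decreasing_and_conservative(self, values):
        cre = cumulative_re(values)
        if cre.size:
            assert (np.diff(cre) >= -1e-12).all()
            increments = np.diff(np.concatenate([[0.0], cre]))
            assert cre[-1] == pytest.approx(increments.sum())


class TestGroupSummary:
    def test_printed_cv_convention(self):
        # mean 40.5, sd 3.3 as data moments -> CV 8.1% at 1 d.p.
        s = group_summary([40.5 - 3.3, 40.5, 40.5 + 3.3])
        assert s.mean == pytest.approx(40.5)
        assert round(s.cv_percent, 1) == round(100 * s.sd / s.mean, 1)

    def test_constant_vector(self):
        s = group_summary([5.0, 5.0, 5.0])
        assert s.sd == 0.0 and s.cv_percent == 0.0

    def test_hand_computed_triplet(self):
        s = group_summary([1, 2, 3])
        assert s.mean == 2 and s.sd == pytest.approx(1.0) and s.cv_percent == pytest.approx(50.0)
        assert (s.max, s.min, s.n) == (3.0, 1.0, 3)

    def test_missing_excluded_and_all_missing_rejected(self):
        s = group_summary([1.0, np.nan, 3.0])
        assert s.n == 2
        with pytest.raises(ValueError):
            group_summary([np.nan, np.nan])


class TestVarianceTrajectory:
    def test_identical_animals_give_zero_variance(self):
        m = np.tile(np.linspace(0.1, 0.2, 5), (4, 1))
        var, trend = variance_trajectory(m)
        assert np.allclose(var, 0)
        assert trend.slope == pytest.approx(0.0, abs=1e-12)

    def test_exactly_linear_variance_recovered(self):
        # two animals +/- d(t) around 0.5 with d chosen for linear variance
        nights = 6
        target_var = 0.01 + 0.002 * np.arange(nights)
        d = np.sqrt(target_var / 2)
        m = np.vstack([0.5 + d, 0.5 - d])
        var, trend = variance_trajectory(m)
        assert np.allclose(var, target_var)
        assert trend.slope == pytest.approx(0.002, abs=1e-12)
        assert trend.adj_r2 == pytest.approx(1.0)

    def test_simulated_decline_sign_recovered(self):
        rng = np.random.default_rng(3)
        nights = 50
        true_slope = -0.0004
        sd = np.sqrt(0.03 + true_slope * np.arange(nights))
        m = rng.normal(0.5, sd, size=(40, nights))
        var, trend = variance_trajectory(m)
        assert trend.slope < 0

    def test_too_few_nights_rejected(self):
        with pytest.raises(ValueError, match="3 nights"):
            variance_trajectory(np.ones((3, 2)))


class TestRoamingSeries:
    def test_missing_mask_and_cre_alignment(self):
        s = RoamingSeries("M01", [1, 2, 3], np.array([0.2, np.nan, 0.1]))
        assert list(s.missing_mask) == [False, True, False]
        assert np.allclose(s.cre, [0.2, 0.2, 0.3])
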