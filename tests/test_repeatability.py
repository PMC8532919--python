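"""Sliding-window ICC repeatability, bootstrap CIs and permutation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roamkit.repeatability import (
    bootstrap_ci,
    estimate_repeatability,
    permutation_pvalue,
    repeatability_trend,
    sliding_windows,
    windowed_repeatability,
)
from roamkit.synthetic import simulate_re_panel


def brute_force_icc(groups):
    """Variance components spelt out from group means and pooled residuals."""
    groups = [np.asarray(g, float) for g in groups]
    a = len(groups)
    sizes = np.array([len(g) for g in groups], float)
    N = sizes.sum()
    allv = np.concatenate(groups)
    grand = allv.mean()
    ms_a = sum(n * (g.mean() - grand) ** 2 for n, g in zip(sizes, groups)) / (a - 1)
    ms_w = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - a)
    n0 = (N - (sizes**2).sum() / N) / (a - 1)
    s_a = max(0.0, (ms_a - ms_w) / n0)
    return s_a / (s_a + ms_w) if (s_a + ms_w) else 0.0


class TestSlidingWindows:
    def test_twenty_weeks_give_seventeen_windows(self):
        assert len(sliding_windows(20, 4, 1)) == 17

    def test_minimum_span_single_window(self):
        ws = sliding_windows(4)
        assert len(ws) == 1
        assert (ws[0].first_week, ws[0].last_week) == (1, 4)

    def test_five_weeks_two_offset_windows(self):
        ws = sliding_windows(5)
        assert [(w.first_week, w.last_week) for w in ws] == [(1, 4), (2, 5)]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_windows(3)


class TestEstimator:
    def test_zero_within_variance_gives_one(self):
        assert estimate_repeatability([[1, 1], [2, 2], [3, 3]]) == 1.0

    def test_identical_group_means_truncate_to_zero(self):
        assert estimate_repeatability([[1, 2], [1, 2], [1, 2]]) == 0.0

    def test_all_equal_degenerate_zero(self):
        assert estimate_repeatability([[3, 3], [3, 3]]) == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            estimate_repeatability([[1, 2, 3]])

    def test_missing_values_dropped(self):
        r1 = estimate_repeatability([[1, 1, np.nan], [2, 2], [3, 3]])
        r2 = estimate_repeatability([[1, 1], [2, 2], [3, 3]])
        assert r1 == r2

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(-10, 10), min_size=2, max_size=8),
            min_size=2,
            max_size=8,
        )
    )
    def test_matches_brute_force_and_stays_in_unit_interval(self, groups):
        r = estimate_repeatability(groups)
        assert 0.0 <= r <= 1.0
        assert r == pytest.approx(brute_force_icc(groups), abs=1e-10)

    def test_unbalanced_groups_match_brute_force(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(i * 0.5, 1, size=n) for i, n in enumerate([3, 9, 5, 12, 2])]
        assert estimate_repeatability(groups) == pytest.approx(
            brute_force_icc(groups), abs=1e-12
        )

    def test_matches_independent_icc11_implementation(self):
        # pingouin's one-way random single-measure ICC(1,1) on balanced data
        import pandas as pd
        import pingouin as pg

        panel, _ = simulate_re_panel(8, 12, 0.5, seed=13)
        long = pd.DataFrame(panel).stack().reset_index()
        long.columns = ["animal", "night", "value"]
        icc_table = pg.intraclass_corr(
            data=long, targets="animal", raters="night", ratings="value"
        )
        reference = float(icc_table.loc[icc_table["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        assert estimate_repeatability(list(panel)) == pytest.approx(reference, abs=1e-10)

    def test_simulated_variance_ratio_recovered(self):
        # sigma2_a = sigma2_e -> true ICC 0.5 at 19 animals x 28 nights
        ests = [
            estimate_repeatability(list(simulate_re_panel(19, 28, 0.5, seed=s)[0]))
            for s in range(200)
        ]
        assert np.mean(ests) == pytest.approx(0.5, abs=0.05)


class TestBootstrap:
    def test_degenerate_data_interval_collapses(self):
        ci = bootstrap_ci([[1, 1], [2, 2], [3, 3]], n_boot=50, seed=0)
        assert ci == (1.0, 1.0)

    def test_same_seed_identical(self):
        groups = list(simulate_re_panel(8, 10, 0.5, seed=4)[0])
        assert bootstrap_ci(groups, seed=11) == bootstrap_ci(groups, seed=11)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_ci([[1, 2], [3, 4]], n_boot=10)

    def test_interval_covers_truth(self):
        # moderate check: 25 trials, ICC 0.5, interval should cover >= 90%
        hits = 0
        for s in range(25):
            groups = list(simulate_re_panel(19, 28, 0.5, seed=200 + s)[0])
            lo, hi = bootstrap_ci(groups, n_boot=200, seed=s)
            hits += lo <= 0.5 <= hi
        assert hits >= 21


class TestPermutation:
    def test_separated_groups_minimum_p(self):
        # groups large enough that no random shuffle can rebuild the separation
        rng = np.random.default_rng(0)
        groups = [rng.normal(mu, 0.01, size=8) for mu in (1.0, 5.0, 9.0)]
        assert permutation_pvalue(groups, n_perm=99, seed=1) == pytest.approx(1 / 100)

    def test_all_equal_p_is_one(self):
        assert permutation_pvalue([[2, 2], [2, 2], [2, 2]], n_perm=50, seed=2) == 1.0

    def test_relabeling_invariance(self):
        # equal group sizes: reordering animals must not change the seeded
        # permutation distribution, hence not the p-value
        groups = list(simulate_re_panel(6, 6, 0.5, seed=9)[0])
        p1 = permutation_pvalue(groups, n_perm=100, seed=5)
        p2 = permutation_pvalue(groups[::-1], n_perm=100, seed=5)
        assert p1 == p2


class TestTrend:
    def test_constant_r_zero_slope(self):
        fit = repeatability_trend([0.4] * 10)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_r_perfect_fit(self):
        fit = repeatability_trend(np.linspace(0.34, 0.62, 17))
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx((0.62 - 0.34) / 16)


class TestIncreasingConsistency:
    def test_growing_between_animal_spread_gives_positive_r_trend(self):
        # construct a panel whose generating ICC rises across windows: the
        # animal effect is scaled up linearly over 20 weeks of nights
        import pandas as pd

        rng = np.random.default_rng(6)
        n_animals, n_nights = 12, 20 * 7
        a = rng.normal(0, 1.0, size=(n_animals, 1))
        e = rng.normal(0, 1.0, size=(n_animals, n_nights))
        scale = np.linspace(0.3, 2.0, n_nights)  # ICC 0.08 -> 0.8
        panel = a * scale + e
        dates = pd.date_range("2019-06-01", periods=n_nights).date
        table = pd.DataFrame(
            [
                {"animal_id": f"M{i}", "date": d, "re": panel[i, t]}
                for i in range(n_animals)
                for t, d in enumerate(dates)
            ]
        )
        res = windowed_repeatability(table, n_weeks=20, n_boot=20, n_perm=10, seed=1)
        assert len(res) == 17
        trend = repeatability_trend(res["R"].to_numpy())
        assert trend.slope > 0
        assert res["R"].iloc[-1] > res["R"].iloc[0]


class TestWindowedPipeline:
    def test_windowed_repeatability_table(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        panel, _ = simulate_re_panel(6, 5 * 7, 0.6, seed=3)
        dates = pd.date_range("2019-06-01", periods=35).date
        rows = [
            {"animal_id": f"M{i}", "date": d, "re": panel[i, t]}
            for i in range(6)
            for t, d in enumerate(dates)
        ]
        table = pd.DataFrame(rows)
        res = windowed_repeatability(table, n_boot=50, n_perm=20, seed=42)
        assert len(res) == 2  # 5 analysed weeks -> windows 1-4 and 2-5
        assert ((res["R"] >= 0) & (res["R"] <= 1)).all()
        assert (res["ci_low"] <= res["ci_high"]).all()
        again = windowed_repeatability(table, n_boot=50, n_perm=20, seed=42)
        assert res.equals(again)
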