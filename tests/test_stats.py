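"""Nonparametric tests, FDR, heatmap tables, matching, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hepatoflux import (
    bh_fdr,
    group_median_zscale,
    kruskal_wallis,
    linear_validation,
    mann_whitney,
    match_cohorts,
    spearman,
)
from hepatoflux.stats import StatsError


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_symmetric(self):
        assert mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1.0])

    def test_power_at_two_sd_shift(self):
        """n=50 per group, 2-SD shift: rejects at alpha=0.05 in >=95% of
        200 simulations."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 50)
            b = rng.normal(2, 1, 50)
            if mann_whitney(a, b).p_value < 0.05:
                hits += 1
        assert hits >= 190


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            kruskal_wallis([[1.0, 2.0]])

    def test_null_uniformity(self):
        """Label permutation of null data: rejection near nominal 5%."""
        hits = 0
        n_seeds = 400
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 40)
            groups = np.array_split(x, 4)
            if kruskal_wallis(groups).p_value < 0.05:
                hits += 1
        lo, hi = sps.binom.interval(0.99, n_seeds, 0.05)
        assert lo <= hits <= hi

    def test_power_under_monotone_shift(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(mu, 1, 20) for mu in (0.0, 0.7, 1.4, 2.1)]
            if kruskal_wallis(groups).p_value < 0.05:
                hits += 1
        assert hits >= 190


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 5], [2, 4, 9, 20])
        assert rho == pytest.approx(1.0)

    def test_perfect_reversal(self):
        rho, _ = spearman([1, 2, 3, 5], [20, 9, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_exhaustive_rank_formula(self):
        """rho equals the brute-force average-rank computation on random
        n=6 samples (with possible ties)."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            x = rng.integers(0, 4, 6).astype(float)
            y = rng.integers(0, 4, 6).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, _ = spearman(x, y)
            rx = sps.rankdata(x)
            ry = sps.rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(expected, abs=1e-12)


class TestBhFdr:
    def test_step_up_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_fdr([0.5, 1.5])

    def test_monotone_dominating_and_capped(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(0, 1, 20))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        # re-adjustment only pushes values further up, never below
        assert np.all(bh_fdr(q) >= q - 1e-12)


class TestGroupMedianZscale:
    def test_single_group_centers_near_zero(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"a": rng.normal(5, 2, 30), "b": rng.normal(0, 1, 30)})
        heat = group_median_zscale(table, pd.Series(["g"] * 30))
        assert np.all(np.abs(heat.to_numpy()) < 0.5)

    def test_mirror_groups_symmetric(self):
        x = np.array([1.0, 2.0, 3.0])
        table = pd.DataFrame({"v": np.concatenate([x, -x])})
        heat = group_median_zscale(table, pd.Series(["p"] * 3 + ["n"] * 3))
        assert heat.loc["p", "v"] == pytest.approx(-heat.loc["n", "v"])

    def test_matches_direct_computation(self):
        table = pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "b": [2.0, 2.0, 8.0, 8.0, 5.0, 5.0],
            "c": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        })
        groups = pd.Series(["x", "x", "y", "y", "z", "z"])
        heat = group_median_zscale(table, groups)
        z = (table - table.mean()) / table.std(ddof=1)
        for g in ("x", "y", "z"):
            for col in table.columns:
                assert heat.loc[g, col] == pytest.approx(
                    z.loc[groups[groups == g].index, col].median())

    def test_zero_variance_dropped_with_warning(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "flat": [1.0] * 4})
        with pytest.warns(UserWarning, match="flat"):
            heat = group_median_zscale(table, pd.Series(["g", "g", "h", "h"]))
        assert "flat" not in heat.columns


def _cohort_frame(ids, sex, t2d, age, weight):
    return pd.DataFrame({
        "id": ids, "sex": sex, "t2d": t2d, "age": age, "weight": weight,
    })


class TestMatchCohorts:
    FEATURES = ["age", "weight"]

    def test_identical_tables_identity_pairing(self):
        a = _cohort_frame(["a1", "a2"], ["male", "female"], [False, True],
                          [50, 60], [80.0, 90.0])
        b = a.copy()
        b["id"] = ["b1", "b2"]
        res = match_cohorts(a, b, self.FEATURES)
        assert res.pairs["distance"].max() == pytest.approx(0.0)
        assert sorted(zip(res.pairs["id_a"], res.pairs["id_b"])) == [
            ("a1", "b1"), ("a2", "b2")]

    def test_single_pair(self):
        a = _cohort_frame(["a1"], ["male"], [False], [44], [70.0])
        b = _cohort_frame(["b1"], ["male"], [False], [58], [95.0])
        res = match_cohorts(a, b, self.FEATURES)
        assert len(res.pairs) == 1

    def test_strata_forbid_cross_level_pairs(self):
        a = _cohort_frame(["a1"], ["male"], [True], [50], [80.0])
        b = _cohort_frame(["b1"], ["male"], [False], [50], [80.0])
        res = match_cohorts(a, b, self.FEATURES)
        assert len(res.pairs) == 0
        assert res.unmatched_a == ["a1"] and res.unmatched_b == ["b1"]

    def test_optimal_matches_exhaustive_assignment_on_3x3(self):
        rng = np.random.default_rng(77)
        a = _cohort_frame([f"a{i}" for i in range(3)], ["male"] * 3,
                          [False] * 3, rng.integers(40, 70, 3),
                          rng.uniform(60, 110, 3))
        b = _cohort_frame([f"b{i}" for i in range(3)], ["male"] * 3,
                          [False] * 3, rng.integers(40, 70, 3),
                          rng.uniform(60, 110, 3))
        res = match_cohorts(a, b, self.FEATURES, method="optimal")
        # brute force over all 3! pairings on the same standardized features
        pooled = pd.concat([a[self.FEATURES], b[self.FEATURES]])
        za = (a[self.FEATURES] - pooled.mean()) / pooled.std(ddof=1)
        zb = (b[self.FEATURES] - pooled.mean()) / pooled.std(ddof=1)
        best = min(
            sum(np.linalg.norm(za.iloc[i] - zb.iloc[p[i]]) for i in range(3))
            for p in itertools.permutations(range(3))
        )
        assert res.total_distance == pytest.approx(best, abs=1e-9)

    def test_greedy_not_worse_than_twice_optimal_here(self):
        rng = np.random.default_rng(5)
        a = _cohort_frame([f"a{i}" for i in range(4)], ["female"] * 4,
                          [True] * 4, rng.integers(40, 70, 4),
                          rng.uniform(60, 110, 4))
        b = _cohort_frame([f"b{i}" for i in range(4)], ["female"] * 4,
                          [True] * 4, rng.integers(40, 70, 4),
                          rng.uniform(60, 110, 4))
        greedy = match_cohorts(a, b, self.FEATURES, method="greedy")
        optimal = match_cohorts(a, b, self.FEATURES, method="optimal")
        assert greedy.total_distance >= optimal.total_distance - 1e-12
        assert greedy.total_distance <= 2 * optimal.total_distance + 1e-12

    def test_missing_feature_rejected(self):
        a = _cohort_frame(["a1"], ["male"], [False], [50], [80.0])
        with pytest.raises(StatsError, match="bmi"):
            match_cohorts(a, a, ["bmi"])


class TestLinearValidation:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = linear_validation(x, x)
        assert res["slope"] == pytest.approx(1.0)
        assert res["r"] == pytest.approx(1.0)
        assert res["bias"] == pytest.approx(0.0)

    def test_affine_noiseless(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = linear_validation(x, 2 * x + 1)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            linear_validation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_recovers_programmed_coupling(self):
        """Correlation between coupled noisy fluxes reflects the programmed
        association across seeds."""
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(10, 2, 40)
            y = x + rng.normal(0, 2, 40)  # true r = 1/sqrt(2) ~ 0.71
            rs.append(linear_validation(x, y)["r"])
        assert np.mean(rs) == pytest.approx(1 / np.sqrt(2), abs=0.1)
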