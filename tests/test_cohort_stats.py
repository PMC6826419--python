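"""Rank tests, survival comparison, t/F tests and their exact variants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cateno_iso import (
    band_ratio,
    kruskal_dunn,
    logrank,
    ratio_vs_size,
    simulate_cohort,
    simulate_scores,
    spearman_assoc,
    subregion_compare,
    survival_by_ratio,
    ttest_with_f,
)
from cateno_iso.synthetic import CohortSimConfig


class TestBandRatio:
    def test_arithmetic(self):
        bands = pd.DataFrame({"p120_1": [1000, 500], "p120_3": [3000, 500]})
        np.testing.assert_allclose(band_ratio(bands), [3.0, 1.0])

    def test_zero_denominator_flagged(self):
        bands = pd.DataFrame({"p120_1": [0, 100], "p120_3": [50, 100]})
        with pytest.warns(UserWarning, match="zero p120-1"):
            r = band_ratio(bands)
        assert np.isnan(r.iloc[0]) and r.iloc[1] == 1.0


def kw_h_oracle(groups):
    """Hand rank computation: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2,
    with the standard tie correction."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    _, cnt = np.unique(pooled, return_counts=True)
    return h / (1 - np.sum(cnt**3 - cnt) / (n**3 - n))


def permutation_p_kw(groups):
    """Exhaustive permutation distribution of H over all distinct label
    assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = kw_h_oracle(groups)
    count = total = 0
    for perm in set(itertools.permutations(range(len(pooled)))):
        vals, start, gs = pooled[list(perm)], 0, []
        for s in sizes:
            gs.append(vals[start:start + s])
            start += s
        if kw_h_oracle(gs) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestKruskalDunn:
    def test_hand_computed_h(self):
        res = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.H == pytest.approx(7.2)

    def test_identical_constant_groups(self):
        res = kruskal_dunn([[5, 5, 5], [5, 5, 5]])
        assert res.H == 0.0 and res.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([[1, 2], []])

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.0, 2.5, 3.0], [4.0, 5.5], [0.5, 6.0, 7.0]],
            [[10, 12, 11], [13, 15, 14, 16]],
            [[1, 1, 2], [2, 3, 3], [4, 5]],
        ],
    )
    def test_exact_p_matches_exhaustive_permutation(self, groups):
        res = kruskal_dunn(groups, exact=True)
        assert res.p == pytest.approx(permutation_p_kw(groups))

    def test_dunn_z_against_direct_formula(self):
        groups = [[1, 2, 3, 10], [4, 5, 6], [7, 8, 9]]
        res = kruskal_dunn(groups, adjust="none")
        pooled = np.concatenate([np.asarray(g, float) for g in groups])
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        r1, r2 = ranks[:4].mean(), ranks[4:7].mean()
        se = np.sqrt(n * (n + 1) / 12 * (1 / 4 + 1 / 3))
        z_expected = (r1 - r2) / se
        row = res.dunn.iloc[0]
        assert row["z"] == pytest.approx(z_expected)
        assert row["p_adj"] == pytest.approx(row["p_unadj"])

    def test_dunn_exact_p_matches_permutation_oracle(self):
        groups = [[1.0, 4.0, 2.0], [3.0, 6.0], [5.0, 8.0, 7.0]]
        res = kruskal_dunn(groups, exact=True, adjust="none")
        pooled = np.concatenate(groups)
        sizes = [3, 2, 3]
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        var = n * (n + 1) / 12  # no ties here
        pairs = [(0, 1), (0, 2), (1, 2)]
        # oracle: permute labels, recompute each |z|
        z_obs = np.abs(res.dunn["z"].to_numpy())
        counts = np.zeros(3)
        total = 0
        for assign in itertools.permutations(range(n)):
            means, start = [], 0
            for s in sizes:
                means.append(ranks[list(assign[start:start + s])].mean())
                start += s
            for k, (i, j) in enumerate(pairs):
                se = np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
                if abs((means[i] - means[j]) / se) >= z_obs[k] - 1e-12:
                    counts[k] += 1
            total += 1
        np.testing.assert_allclose(res.dunn["p_unadj"], counts / total)

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 2.0, 7.0], [3.0, 9.0], [4.0, 5.0, 6.0]]
        r1 = kruskal_dunn(groups)
        r2 = kruskal_dunn([np.exp(np.asarray(g)) for g in groups])
        assert r1.H == pytest.approx(r2.H)
        np.testing.assert_allclose(r1.dunn["z"], r2.dunn["z"])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_assoc([1, 2, 3, 4], [10, 20, 30, 40]).rho == 1.0
        assert spearman_assoc([1, 2, 3, 4], [8, 6, 4, 2]).rho == -1.0

    def test_ties_equal_pearson_on_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        rho = spearman_assoc(x, y).rho
        expected = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert rho == pytest.approx(expected)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman_assoc([1, 1, 1], [1, 2, 3])
        assert res.undefined and np.isnan(res.rho)


def mantel_cox_oracle(times, events, in_a):
    """Hand risk-table computation of the log-rank chi-square."""
    o_e = v = 0.0
    for t in sorted(set(times[events])):
        at = times >= t
        n, na = at.sum(), (at & in_a).sum()
        d = ((times == t) & events).sum()
        da = ((times == t) & events & in_a).sum()
        o_e += da - d * na / n
        if n > 1:
            v += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return 0.0 if v == 0 else o_e**2 / v


class TestLogrank:
    def test_identical_groups(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        res = logrank(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_toy_example_matches_hand_computation(self):
        ta, ea = np.array([2.0, 4.0]), np.array([True, True])
        tb, eb = np.array([1.0, 3.0]), np.array([True, False])
        res = logrank(ta, ea, tb, eb)
        times = np.concatenate([ta, tb])
        events = np.concatenate([ea, eb])
        in_a = np.array([True, True, False, False])
        assert res.chi2 == pytest.approx(mantel_cox_oracle(times, events, in_a))

    def test_exact_p_matches_exhaustive_permutation(self):
        ta, ea = np.array([2.0, 4.0, 6.0, 9.0]), np.array([1, 1, 0, 1], bool)
        tb, eb = np.array([1.0, 3.0, 5.0, 7.0]), np.array([1, 1, 1, 0], bool)
        res = logrank(ta, ea, tb, eb, exact=True)
        times = np.concatenate([ta, tb])
        events = np.concatenate([ea, eb])
        chi_obs = mantel_cox_oracle(times, events,
                                    np.arange(8) < 4)
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(combo)] = True
            if mantel_cox_oracle(times, events, mask) >= chi_obs - 1e-12:
                count += 1
            total += 1
        assert res.chi2 == pytest.approx(chi_obs)
        assert res.p == pytest.approx(count / total)

    def test_no_events_flagged(self):
        with pytest.warns(UserWarning, match="no events"):
            res = logrank([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.undefined

    def test_power_under_hazard_ratio_three(self):
        """Exponential survival, HR 3, n = 100/arm: significant in >= 90%
        of replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 200
        for _ in range(reps):
            ta = rng.exponential(1 / 0.06, 100)
            tb = rng.exponential(1 / 0.02, 100)
            res = logrank(ta, np.ones(100, bool), tb, np.ones(100, bool))
            hits += res.p < 0.05
        assert hits / reps >= 0.9


class TestPatientAnalyses:
    @pytest.fixture
    def records(self):
        rec, _ = simulate_cohort(CohortSimConfig(n_patients=120), seed=5)
        return rec

    def test_ratio_vs_size_delegates_to_kruskal(self, records):
        res = ratio_vs_size(records)
        groups = [records.loc[records["size_category"] == c, "ratio"].to_numpy()
                  for c in ("T1", "T2", "T3")]
        direct = kruskal_dunn(groups, group_names=["T1", "T2", "T3"])
        assert res.H == pytest.approx(direct.H)
        np.testing.assert_allclose(res.dunn["z"], direct.dunn["z"])

    def test_identical_ratios_across_sizes_null(self, records):
        flat = records.copy()
        flat["ratio"] = np.tile([1.0, 2.0, 3.0], len(flat))[: len(flat)]
        # shuffle-free: same multiset in every stratum is not guaranteed,
        # so use truly constant ratios instead
        flat["ratio"] = 1.0
        res = ratio_vs_size(flat)
        assert res.p == 1.0

    def test_shifted_t3_ratio_detected(self):
        cfg = CohortSimConfig(n_patients=90, size_effect=1.0,
                              grade_effect=0.0, size_probs=(1/3, 1/3, 1/3))
        rec, _ = simulate_cohort(cfg, seed=8)
        assert ratio_vs_size(rec).p < 0.05

    def test_median_split_balances_arms(self):
        rec = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(10)],
            "ratio": np.arange(10, dtype=float),
            "grade": [1] * 10,
            "size_category": ["T1"] * 10,
            "survival_time": np.arange(1.0, 11.0),
            "event": [True] * 10,
        })
        high = rec["ratio"] > rec["ratio"].median()
        assert high.sum() == 5
        res = survival_by_ratio(rec)
        assert np.isfinite(res.chi2)

    def test_identical_arms_null(self):
        base = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(8)],
            "ratio": [1, 1, 1, 1, 9, 9, 9, 9],
            "grade": [1] * 8,
            "size_category": ["T1"] * 8,
            "survival_time": [2.0, 4.0, 6.0, 8.0] * 2,
            "event": [True, True, False, True] * 2,
        })
        res = survival_by_ratio(base)
        assert res.p == pytest.approx(1.0)

    def test_high_ratio_hazard_detected(self):
        cfg = CohortSimConfig(n_patients=100, hazard_ratio=2.5,
                              censoring_rate=0.1)
        rec, _ = simulate_cohort(cfg, seed=9)
        assert survival_by_ratio(rec).p < 0.05

    def test_empty_arm_rejected(self):
        rec = pd.DataFrame({
            "patient_id": ["a", "b"],
            "ratio": [1.0, 1.0],
            "grade": [1, 1],
            "size_category": ["T1", "T1"],
            "survival_time": [1.0, 2.0],
            "event": [True, True],
        })
        with pytest.raises(ValueError, match="arm"):
            survival_by_ratio(rec)


class TestTTestWithF:
    def test_identical_groups(self):
        res = ttest_with_f([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)
        assert res.f == pytest.approx(1.0) and res.f_p == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        a = [9.0, 10.0, 11.0]
        b = [11.0, 12.0, 13.0]
        res = ttest_with_f(a, b)
        sp = np.sqrt(((2) * 1.0 + (2) * 1.0) / 4)  # pooled sd = 1
        expected_t = (10.0 - 12.0) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert res.t == pytest.approx(expected_t)
        assert not res.unequal_variance_warning

    def test_unequal_variance_warned(self):
        a = np.array([0.0, 0.001, -0.001, 0.0005, -0.0005])
        b = np.array([0.0, 10.0, -10.0, 5.0, -5.0])
        with pytest.warns(UserWarning, match="F-test rejects"):
            res = ttest_with_f(a, b)
        assert res.unequal_variance_warning

    def test_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = ttest_with_f([2.0, 2.0], [2.0, 2.0])
        assert res.undefined


class TestSubregionScores:
    def test_all_high_everywhere_null(self):
        rows = [("s%d" % i, sub, "p120_1", 2)
                for sub in ("in situ", "fibrous invasion")
                for i in range(5)]
        table = pd.DataFrame(rows, columns=["specimen", "subregion",
                                            "marker", "score"])
        res = subregion_compare(table, "p120_1")
        assert res.p == 1.0

    def test_extreme_pattern_matches_permutation_oracle(self):
        rows = ([("a%d" % i, "in situ", "p120_1", 2) for i in range(6)]
                + [("b%d" % i, "fibrous invasion", "p120_1", 0)
                   for i in range(2)])
        table = pd.DataFrame(rows, columns=["specimen", "subregion",
                                            "marker", "score"])
        res = subregion_compare(table, "p120_1", exact=True)
        # 2 zeros among 8 slots; only the observed split is as extreme
        assert res.p == pytest.approx(1 / 28)

    def test_delegation_equals_kruskal_on_codes(self):
        table, _ = simulate_scores(8, "invasion_shift", seed=2)
        res = subregion_compare(table, "p120_1")
        df = table[table["marker"] == "p120_1"]
        groups, names = [], []
        for sub in df["subregion"].unique():
            groups.append(df.loc[df["subregion"] == sub, "score"].to_numpy(float))
            names.append(sub)
        # same groups, possibly different order -> compare omnibus only
        direct = kruskal_dunn(groups, group_names=names)
        assert res.H == pytest.approx(direct.H)

    def test_two_rater_consensus_average(self):
        table = pd.DataFrame({
            "specimen": ["s1", "s2", "s3", "s4"],
            "subregion": ["in situ"] * 2 + ["fibrous invasion"] * 2,
            "marker": ["p120_1"] * 4,
            "rater1": [2, 1, 0, 0],
            "rater2": [1, 1, 1, 0],
        })
        from cateno_iso.cohort_stats import consensus_scores

        out = consensus_scores(table)
        np.testing.assert_array_equal(out["score"], [2.0, 1.0, 1.0, 0.0])
        with pytest.warns(UserWarning, match="discordant"):
            strict = consensus_scores(table, rule="strict")
        assert np.isnan(strict["score"].iloc[0])
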