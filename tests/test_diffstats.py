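"""Kruskal-Wallis, Bonferroni, rank LSD post-hoc, correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldiprof.binning import FeatureMatrix
from maldiprof.diffstats import (
    StatsConfig,
    bonferroni_adjust,
    feature_correlation,
    kruskal_wallis,
    lsd_posthoc,
    run_differential_analysis,
)
from maldiprof.errors import ValidationError


def _rank_H(values, labels, uniq):
    """Independent tie-corrected H computed directly from ranks."""
    from scipy.stats import rankdata

    r = rankdata(values)
    N = len(values)
    rbar = (N + 1) / 2
    H = 0.0
    for g in uniq:
        sel = r[labels == g]
        H += sel.size * (sel.mean() - rbar) ** 2
    H *= 12 / (N * (N + 1))
    _, counts = np.unique(values, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / tie if tie > 0 else 0.0


class TestKruskalWallis:
    def test_all_values_equal_gives_p_one(self):
        values = np.ones(9)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        H, p = kruskal_wallis(values, groups)
        assert H == 0.0
        assert p == 1.0

    def test_complete_separation_closed_form(self):
        # groups {1,2,3},{4,5,6},{7,8,9}: H = 12/(9*10) * 3*((2-5)^2+0+(8-5)^2)
        values = np.arange(1.0, 10.0)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        H, p = kruskal_wallis(values, groups)
        assert H == pytest.approx(7.2)
        assert 0 < p < 0.05

    def test_group_with_single_sample_errors(self):
        with pytest.raises(ValidationError):
            kruskal_wallis(np.arange(5.0), ["a", "a", "a", "a", "b"])

    def test_p_matches_permutation_oracle(self, rng):
        """Chi-square p agrees with the permutation null in the
        significance-relevant tail at small n (groups of 4)."""
        values = np.array([1.0, 2.5, 0.8, 3.1, 2.0, 3.3, 4.9, 3.4,
                           6.0, 2.8, 6.2, 4.5])
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        uniq = ["a", "b", "c"]
        H_obs, p_chi2 = kruskal_wallis(values, labels)
        assert H_obs == pytest.approx(_rank_H(values, labels, uniq), rel=1e-9)
        n_draws = 20_000
        count = 0
        for _ in range(n_draws):
            perm = rng.permutation(labels)
            if _rank_H(values, perm, uniq) >= H_obs - 1e-12:
                count += 1
        p_perm = count / n_draws
        assert p_chi2 == pytest.approx(p_perm, abs=0.02)

    def test_permutation_method_matches_independent_oracle(self, rng):
        """The built-in Monte-Carlo permutation p agrees with an
        independently coded permutation estimate at any p level."""
        values = np.array([3.1, 0.2, 1.5, 4.8, 5.2, 2.9, 0.7, 6.4,
                           2.2, 5.9, 1.1, 4.0])
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        H_obs, p_builtin = kruskal_wallis(values, labels, method="permutation",
                                          n_permutations=10_000, seed=12)
        count = sum(
            _rank_H(values, rng.permutation(labels), ["a", "b", "c"])
            >= H_obs - 1e-12
            for _ in range(10_000)
        )
        assert p_builtin == pytest.approx(count / 10_000, abs=0.03)


class TestBonferroni:
    def test_identity_and_cap(self):
        assert bonferroni_adjust(0.01, 1) == 0.01
        assert bonferroni_adjust(0.5, 57) == 1.0

    def test_arithmetic(self):
        assert bonferroni_adjust(3.0e-5, 57) == pytest.approx(1.71e-3)

    def test_invalid_n_tests(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust(0.5, 0)

    @settings(max_examples=50)
    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.integers(min_value=1, max_value=500),
    )
    def test_monotone_in_raw_p_and_capped(self, p1, p2, n):
        lo, hi = sorted([p1, p2])
        a_lo, a_hi = bonferroni_adjust(lo, n), bonferroni_adjust(hi, n)
        assert a_lo <= a_hi <= 1.0
        assert a_lo >= lo


class TestLsdPosthoc:
    def test_identical_groups_no_difference(self):
        values = np.tile([1.0, 2.0, 3.0], 3)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        decisions, _ = lsd_posthoc(values, groups)
        assert not decisions.to_numpy().any()

    def test_planted_ordering_recovered(self, rng):
        low = rng.normal(0, 1, 9)
        mid = rng.normal(10, 1, 9)
        high = rng.normal(20, 1, 9)
        values = np.concatenate([mid, low, high])
        groups = ["wt"] * 9 + ["null"] * 9 + ["oe"] * 9
        decisions, order = lsd_posthoc(values, groups, alpha=0.05)
        assert order == ["null", "wt", "oe"]
        for a in ("wt", "null", "oe"):
            for b in ("wt", "null", "oe"):
                if a != b:
                    assert decisions.loc[a, b]

    def test_agrees_with_pairwise_permutation_test(self, rng):
        """Decisions match a permutation rank-mean test on small instances."""
        agreements = 0
        trials = 40
        for t in range(trials):
            n = 5
            shift = rng.choice([0.0, 2.5])
            x = rng.normal(0, 1, n)
            y = rng.normal(shift, 1, n)
            values = np.concatenate([x, y])
            groups = ["a"] * n + ["b"] * n
            decisions, _ = lsd_posthoc(values, groups, alpha=0.05)
            from scipy.stats import rankdata

            ranks = rankdata(values)
            obs = abs(ranks[:n].mean() - ranks[n:].mean())
            count = 0
            for _ in range(2000):
                perm = rng.permutation(ranks)
                if abs(perm[:n].mean() - perm[n:].mean()) >= obs - 1e-12:
                    count += 1
            perm_different = (count / 2000) < 0.05
            agreements += decisions.loc["a", "b"] == perm_different
        assert agreements / trials >= 0.95


class TestFeatureCorrelation:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert feature_correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert feature_correlation(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        ) == pytest.approx(0.9643, abs=1e-4)

    def test_orthogonal_vectors_near_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert feature_correlation(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValidationError):
            feature_correlation(np.ones(5), np.arange(5.0))


class TestRunDifferentialAnalysis:
    def test_single_null_feature_not_significant(self):
        matrix = FeatureMatrix(
            ["f"], [f"s{i}" for i in range(6)],
            np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]),
            ["a"] * 3 + ["b"] * 3,
        )
        (res,) = run_differential_analysis(matrix)
        assert res.adjusted_p == 1.0
        assert not res.significant
        assert res.posthoc is None

    def test_planted_feature_flagged_among_nulls(self, rng):
        n_feat, n_per = 30, 9
        groups = ["null"] * n_per + ["wt"] * n_per + ["oe"] * n_per
        values = rng.lognormal(0, 0.3, size=(n_feat, 3 * n_per))
        folds = np.concatenate([np.zeros(n_per), np.ones(n_per), 5 * np.ones(n_per)])
        values[7] = folds * rng.lognormal(0, 0.3, size=3 * n_per)
        matrix = FeatureMatrix(
            [f"f{i}" for i in range(n_feat)],
            [f"s{j}" for j in range(3 * n_per)], values, groups,
        )
        results = run_differential_analysis(matrix)
        top = results[0]
        assert top.feature_id == "f7"
        assert top.significant
        assert top.mean_rank_order == ["null", "wt", "oe"]

    def test_bonferroni_uses_distribution_count(self, rng):
        n_feat = 10
        values = rng.uniform(0.1, 1, size=(n_feat, 8))
        matrix = FeatureMatrix(
            [f"f{i}" for i in range(n_feat)],
            [f"s{j}" for j in range(8)], values, ["a"] * 4 + ["b"] * 4,
        )
        for r in run_differential_analysis(matrix):
            assert r.adjusted_p == pytest.approx(min(1.0, r.raw_p * n_feat))
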