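"""Spearman correlation cells, one-way ANOVA, post-hoc compact letters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soilsom.errors import ConfigError, DataError
from soilsom.stats import (NOT_COMPUTABLE, anova_oneway, cluster_summary,
                           compact_letters, correlation_table,
                           format_correlation_table, posthoc_letters, spearman)


class TestSpearman:
    def test_identity_and_monotone_transform(self, rng):
        x = rng.normal(size=20)
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        y = rng.normal(size=20)
        base = spearman(x, y).rho
        assert spearman(x ** 3, y).rho == pytest.approx(base, abs=1e-12)

    def test_constant_input_not_computable(self, rng):
        cell = spearman(np.full(10, 2.0), rng.normal(size=10))
        assert cell.flag == "not_computable"
        assert cell.format() == NOT_COMPUTABLE

    def test_rho_matches_scipy_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 5, 25).astype(float)  # heavy ties
            y = rng.integers(0, 5, 25).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            expected = sps.spearmanr(x, y).statistic
            assert spearman(x, y).rho == pytest.approx(expected, abs=1e-10)

    def test_rho_equals_pearson_on_ranks(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert spearman(x, y).rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        # n = 5 distinct monotone: only 2 of 120 permutations reach |rho| = 1
        cell = spearman([1.0, 2, 3, 4, 5], [2.0, 4, 6, 8, 10])
        assert cell.rho == pytest.approx(1.0)
        assert cell.p_value == pytest.approx(2 / 120)

    def test_t_approximation_large_n(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.5, size=40)
        cell = spearman(x, y)
        scipy_p = sps.spearmanr(x, y).pvalue
        assert cell.p_value == pytest.approx(scipy_p, rel=0.05)
        assert cell.flag == "p<0.01"

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            spearman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelationTable:
    def test_perfect_covariate_flagged(self, rng):
        n = 8
        ri = rng.normal(size=n)
        data = pd.DataFrame({"v": ri, "w": rng.normal(size=n)})
        tab = correlation_table(data, ri, np.zeros(n, dtype=int))
        cell = tab.loc["v", 0]
        assert cell.rho == pytest.approx(1.0)
        assert cell.flag == "p<0.01"

    def test_constant_in_one_cluster_only(self, rng):
        labels = np.repeat([1, 2], 10)
        data = pd.DataFrame({"v": rng.normal(size=20)})
        data.loc[labels == 2, "v"] = 5.0
        ri = rng.normal(size=20)
        tab = correlation_table(data, ri, labels)
        assert tab.loc["v", 1].flag != "not_computable"
        assert tab.loc["v", 2].flag == "not_computable"
        rendered = format_correlation_table(tab)
        assert rendered.loc["v", 2] == NOT_COMPUTABLE

    def test_shape_covariates_by_clusters(self, rng):
        n, k = 60, 3
        data = pd.DataFrame(rng.normal(size=(n, 19)),
                            columns=[f"c{i}" for i in range(19)])
        tab = correlation_table(data, rng.normal(size=n), rng.integers(1, k + 1, n))
        assert tab.shape == (19, k)

    def test_small_cluster_not_computable(self, rng):
        labels = np.array([1, 1, 1, 1, 2, 2])
        data = pd.DataFrame({"v": rng.normal(size=6)})
        tab = correlation_table(data, rng.normal(size=6), labels)
        assert tab.loc["v", 2].flag == "not_computable"


class TestAnova:
    def test_equal_means_f_near_zero(self, rng):
        v = np.concatenate([rng.normal(5, 1, 50), rng.normal(5, 1, 50)])
        g = np.repeat([1, 2], 50)
        f, p = anova_oneway(v, g)
        assert f < 4.0 and p > 0.01  # no real signal

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        f, p = anova_oneway(np.concatenate([a, b]), np.repeat([0, 1], [12, 15]))
        t, pt = sps.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_matches_scipy_oneway(self, rng):
        groups = [rng.normal(m, 1, 20) for m in (0.0, 0.5, 2.0)]
        v = np.concatenate(groups)
        g = np.repeat([0, 1, 2], 20)
        f, p = anova_oneway(v, g)
        sf, sp_ = sps.f_oneway(*groups)
        assert f == pytest.approx(sf, rel=1e-10)
        assert p == pytest.approx(sp_, rel=1e-10)

    def test_scale_invariance(self, rng):
        v = rng.normal(size=45)
        g = rng.integers(0, 3, 45)
        f1, _ = anova_oneway(v, g)
        f2, _ = anova_oneway(1000.0 * v, g)
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_small_group_dropped(self, rng):
        v = np.concatenate([rng.normal(size=10), rng.normal(size=10), [9.9]])
        g = np.array([0] * 10 + [1] * 10 + [2])
        with pytest.warns(UserWarning, match="dropped"):
            f, _ = anova_oneway(v, g)
        f2, _ = anova_oneway(v[:20], g[:20])
        assert f == pytest.approx(f2)


class TestPosthocLetters:
    def test_identical_groups_share_letter(self, rng):
        v = rng.normal(5, 1, 120)
        g = np.repeat([1, 2, 3], 40)
        letters = posthoc_letters(v, g)
        assert letters[1] == letters[2] == letters[3] == "a"

    def test_two_far_groups_distinct_letters(self, rng):
        v = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        g = np.repeat(["lo", "hi"], 20)
        letters = posthoc_letters(v, g)
        assert set(letters.values()) == {"a", "b"}

    @pytest.mark.parametrize("method", ["tukey", "duncan"])
    def test_letters_encode_significance_graph(self, rng, method):
        """Groups share a letter iff their pair is non-significant (<= 5 groups)."""
        from soilsom.stats import _group_arrays, _pairwise_significant
        for trial in range(6):
            r = np.random.default_rng(100 + trial)
            k = int(r.integers(3, 6))
            means = r.uniform(0, 6, k)
            arrays = [r.normal(means[i], 1.0, 15) for i in range(k)]
            v = np.concatenate(arrays)
            g = np.repeat(np.arange(k), 15)
            letters = posthoc_letters(v, g, method=method)
            ids, arrs = _group_arrays(v, g)
            sig = _pairwise_significant(arrs, method, 0.05)
            for i, j in itertools.combinations(range(k), 2):
                share = bool(set(letters[ids[i]]) & set(letters[ids[j]]))
                assert share == (not sig[i, j]), (trial, i, j)

    def test_tukey_pairs_match_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        from soilsom.stats import _group_arrays, _pairwise_significant
        v = np.concatenate([rng.normal(m, 1, 18) for m in (0, 0.8, 3.0, 3.2)])
        g = np.repeat(np.arange(4), 18)
        _, arrs = _group_arrays(v, g)
        sig = _pairwise_significant(arrs, "tukey", 0.05)
        sm = pairwise_tukeyhsd(v, g, alpha=0.05)
        expected = list(sm.reject)
        got = [bool(sig[i, j]) for i, j in itertools.combinations(range(4), 2)]
        assert got == expected

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ConfigError):
            posthoc_letters(rng.normal(size=20), np.repeat([0, 1], 10),
                            method="dunn")

    def test_clique_cover_brute_force(self):
        """Letter columns form a clique cover of the non-significance graph."""
        for trial in range(20):
            r = np.random.default_rng(trial)
            k = int(r.integers(2, 6))
            sig = np.zeros((k, k), dtype=bool)
            for i, j in itertools.combinations(range(k), 2):
                sig[i, j] = sig[j, i] = r.random() < 0.4
            letters = compact_letters(sig, list(range(k)))
            # every group lettered; significant pairs never share; ns pairs share
            assert all(letters[g] for g in range(k))
            for i, j in itertools.combinations(range(k), 2):
                share = bool(set(letters[i]) & set(letters[j]))
                assert share == (not sig[i, j])
            # each letter's group set is a clique of the ns-graph (by construction
            # of sharing); verify minimal-cover sanity against brute force size
            cols = {}
            for g, ls in letters.items():
                for c in ls:
                    cols.setdefault(c, set()).add(g)
            best = _min_clique_cover_size(sig, k)
            assert len(cols) >= best  # insert-absorb never beats the optimum
            assert len(cols) <= max(best * 2, k)  # and stays reasonable

    def test_relabeling_permutes_letters(self, rng):
        v = np.concatenate([rng.normal(m, 0.5, 15) for m in (0, 4, 8)])
        g = np.repeat([0, 1, 2], 15)
        l1 = posthoc_letters(v, g)
        l2 = posthoc_letters(v, np.array([{0: 2, 1: 0, 2: 1}[x] for x in g]))
        assert {l1[0], l1[1], l1[2]} == {l2[2], l2[0], l2[1]}


def _min_clique_cover_size(sig, k):
    """Smallest number of non-significance cliques covering all vertices and ns-edges."""
    ns_pairs = [(i, j) for i, j in itertools.combinations(range(k), 2) if not sig[i, j]]
    cliques = [frozenset(s) for r in range(1, k + 1)
               for s in itertools.combinations(range(k), r)
               if all(not sig[a, b] for a, b in itertools.combinations(s, 2))]
    for size in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, size):
            covered_v = set().union(*combo)
            if covered_v != set(range(k)):
                continue
            if all(any({a, b} <= c for c in combo) for a, b in ns_pairs):
                return size
    return k


class TestClusterSummary:
    def test_means_match_groupby_oracle(self, rng):
        data = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        labels = rng.integers(1, 4, 40)
        out = cluster_summary(data, labels)
        oracle = data.groupby(labels).mean().T
        for c in oracle.columns:
            np.testing.assert_allclose(out["means"][c], oracle[c], atol=1e-12)

    def test_singleton_clusters_zero_sd(self, rng):
        data = pd.DataFrame({"v": rng.normal(size=3)})
        out = cluster_summary(data, np.array([1, 2, 3]))
        np.testing.assert_allclose(out["sds"].loc["v"], 0.0)

    def test_row_order_invariance(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        labels = rng.integers(1, 4, 30)
        out1 = cluster_summary(data, labels)
        perm = rng.permutation(30)
        out2 = cluster_summary(data.iloc[perm].reset_index(drop=True), labels[perm])
        assert out1["formatted"].equals(out2["formatted"])

    def test_empty_cluster_column_of_markers(self, rng):
        data = pd.DataFrame({"v": rng.normal(size=20)})
        labels = np.repeat([1, 2], 10)
        out = cluster_summary(data, labels, all_clusters=[1, 2, 3])
        assert (out["formatted"][3] == "-").all()
        assert not (out["formatted"][1] == "-").any()
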