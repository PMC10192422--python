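"""Bk statistic against a brute-force pair-counting oracle (exhaustive
over small partition spaces), null moments against permutation, tree
cutting, and total branch length by explicit edge enumeration."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import fowlkes_mallows_score

from wavecluster.clustering import Dendrogram, DistanceMatrix, ward_cluster
from wavecluster.treestats import (bk_curve, bk_null_moments, bk_statistic,
                                   cut_tree, total_branch_length)


def _pair_counting_oracle(c1: dict, c2: dict) -> float:
    """Independent route: count label pairs co-clustered in both
    partitions; Bk = shared / sqrt(pairs1 * pairs2)."""
    labels = sorted(c1)
    both = p1 = p2 = 0
    for a, b in itertools.combinations(labels, 2):
        in1 = c1[a] == c1[b]
        in2 = c2[a] == c2[b]
        both += in1 and in2
        p1 += in1
        p2 += in2
    if p1 == 0 or p2 == 0:
        return float("nan")
    return both / np.sqrt(p1 * p2)


def _set_partitions(items):
    """All set partitions (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _as_map(partition):
    return {x: i for i, block in enumerate(partition) for x in block}


def _random_tree(labels, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(len(labels), 4))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return ward_cluster(DistanceMatrix(tuple(labels), d, "pearson"))


class TestBkStatistic:
    def test_identical_partitions_give_one(self):
        c = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 2}
        assert bk_statistic(c, c) == pytest.approx(1.0)

    def test_disjoint_pair_structure_gives_zero(self):
        c1 = _as_map([["A", "B"], ["C", "D"]])
        c2 = _as_map([["A", "C"], ["B", "D"]])
        assert bk_statistic(c1, c2) == pytest.approx(0.0)

    def test_six_element_example_matches_oracle(self):
        c1 = _as_map([["A", "B", "C"], ["D", "E", "F"]])
        c2 = _as_map([["A", "B", "D"], ["C", "E", "F"]])
        assert bk_statistic(c1, c2) == pytest.approx(
            _pair_counting_oracle(c1, c2))

    def test_symmetry_and_relabeling_invariance(self):
        c1 = _as_map([["a", "b"], ["c", "d", "e"]])
        c2 = _as_map([["a", "c"], ["b", "d"], ["e"]])
        assert bk_statistic(c1, c2) == pytest.approx(bk_statistic(c2, c1))
        relabeled = {k: 10 - v for k, v in c2.items()}
        assert bk_statistic(c1, relabeled) == pytest.approx(
            bk_statistic(c1, c2))

    def test_all_singletons_undefined(self):
        c1 = {"a": 0, "b": 1, "c": 2}
        c2 = {"a": 0, "b": 0, "c": 1}
        assert np.isnan(bk_statistic(c1, c2))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exhaustive_agreement_with_oracle_small_n(self, n):
        labels = [chr(65 + i) for i in range(n)]
        partitions = [_as_map(p) for p in _set_partitions(labels)]
        for c1 in partitions:
            for c2 in partitions:
                ours = bk_statistic(c1, c2)
                ref = _pair_counting_oracle(c1, c2)
                if np.isnan(ref):
                    assert np.isnan(ours)
                else:
                    assert ours == pytest.approx(ref, abs=1e-12)

    def test_sampled_agreement_with_oracle_and_sklearn_n7(self):
        labels = [chr(65 + i) for i in range(7)]
        partitions = [_as_map(p) for p in _set_partitions(labels)]
        rng = np.random.default_rng(0)
        idx = rng.integers(0, len(partitions), size=(500, 2))
        order = sorted(labels)
        for i, j in idx:
            c1, c2 = partitions[i], partitions[j]
            ours = bk_statistic(c1, c2)
            ref = _pair_counting_oracle(c1, c2)
            if np.isnan(ref):
                assert np.isnan(ours)
                continue
            assert ours == pytest.approx(ref, abs=1e-12)
            sk = fowlkes_mallows_score([c1[x] for x in order],
                                       [c2[x] for x in order])
            assert ours == pytest.approx(sk, abs=1e-9)


class TestCutTree:
    def test_extreme_cuts(self):
        tree = _random_tree(list("abcdefgh"), seed=1)
        top = cut_tree(tree, 2)
        assert len(set(top.values())) == 2
        near_leaves = cut_tree(tree, 7)
        sizes = sorted(np.bincount(list(near_leaves.values())))
        assert sizes == [1, 1, 1, 1, 1, 1, 2]  # one pair, rest singletons

    def test_k_out_of_range_rejected(self):
        tree = _random_tree(list("abcd"), seed=2)
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 5)


class TestBkCurve:
    def test_self_comparison_all_one_and_above_line(self):
        tree = _random_tree([f"t{i}" for i in range(10)], seed=3)
        curve = bk_curve(tree, tree)
        np.testing.assert_allclose(curve.bk, 1.0)
        assert np.all(curve.above_rejection())

    def test_asymptotic_and_permutation_lines_agree_n19(self):
        labels = [f"t{i}" for i in range(19)]
        t1 = _random_tree(labels, seed=4)
        t2 = _random_tree(labels, seed=5)
        ca = bk_curve(t1, t2, null_method="asymptotic")
        cp = bk_curve(t1, t2, null_method="permutation",
                      n_permutations=999, seed=6)
        assert np.nanmax(np.abs(ca.rejection - cp.rejection)) < 0.05

    def test_null_moments_match_monte_carlo(self):
        # direct check of the closed-form mean/sd under random relabeling
        sizes1 = np.array([4, 3, 2, 2])
        sizes2 = np.array([5, 3, 2, 1])
        c1 = {f"x{i}": g for i, g in
              enumerate(np.repeat(np.arange(4), sizes1))}
        base = np.repeat(np.arange(4), sizes2)
        rng = np.random.default_rng(7)
        sims = []
        labels = sorted(c1)
        for _ in range(4000):
            perm = rng.permutation(base)
            sims.append(bk_statistic(c1, dict(zip(labels, perm))))
        mean, sd = bk_null_moments(sizes1, sizes2)
        assert mean == pytest.approx(np.mean(sims), abs=0.01)
        assert sd == pytest.approx(np.std(sims), abs=0.02)

    def test_random_tree_exceedance_near_alpha(self):
        # under unrelated trees the fraction of k above the line ~ alpha
        above = []
        for s in range(60):
            t1 = _random_tree([f"t{i}" for i in range(12)], seed=100 + 2 * s)
            t2 = _random_tree([f"t{i}" for i in range(12)], seed=101 + 2 * s)
            c = bk_curve(t1, t2)
            above.append(np.nanmean(c.above_rejection()))
        assert 0.01 <= np.mean(above) <= 0.12

    def test_mismatched_leaf_sets_listed(self):
        t1 = _random_tree(list("abcd"), seed=8)
        t2 = _random_tree(list("abce"), seed=9)
        with pytest.raises(ValueError, match="symmetric"):
            bk_curve(t1, t2)


class TestTotalBranchLength:
    def test_two_leaves(self):
        Z = np.array([[0.0, 1.0, 2.5, 2.0]])
        assert total_branch_length(Dendrogram(("a", "b"), Z)) == pytest.approx(5.0)

    def test_three_leaf_edge_enumeration(self):
        # (A,B) at h1 = 1, +C at h2 = 3:
        # edges A->m1 (1), B->m1 (1), m1->root (2), C->root (3)
        Z = np.array([[0.0, 1.0, 1.0, 2.0], [2.0, 3.0, 3.0, 3.0]])
        tree = Dendrogram(("A", "B", "C"), Z)
        assert total_branch_length(tree) == pytest.approx(1 + 1 + 2 + 3)

    def test_leaf_order_invariance_and_linear_scaling(self):
        labels = [f"t{i}" for i in range(9)]
        tree = _random_tree(labels, seed=10)
        base = total_branch_length(tree)
        scaled = Dendrogram(tree.labels,
                            tree.Z * np.array([1.0, 1.0, 3.0, 1.0]))
        assert total_branch_length(scaled) == pytest.approx(3 * base)
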