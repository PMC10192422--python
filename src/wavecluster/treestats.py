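"""Quantitative comparison of dendrograms.

The Fowlkes-Mallows ``Bk`` statistic compares the flat ``k``-partitions of
two hierarchical trees.  With ``m_ij`` the number of objects shared
between cluster ``i`` of the first partition and cluster ``j`` of the
second, and ``n`` the number of objects:

    T_k = sum_ij m_ij^2 - n
    P_k = sum_i (sum_j m_ij)^2 - n
    Q_k = sum_j (sum_i m_ij)^2 - n
    B_k = T_k / sqrt(P_k * Q_k)

``B_k`` lies in [0, 1]; 1 means the two k-partitions coincide up to
cluster relabeling.  Tracing ``B_k`` over ``k = 2 .. n-1`` compares two
dendrograms at every resolution.  Significance is judged against the null
of unrelated trees, either through the asymptotic moments of ``B_k``
under random relabeling (Fowlkes & Mallows' formulas, functions of the
marginal cluster sizes) or through an explicit permutation null; the
one-sided upper rejection line is ``mean + z_(1-alpha) * sd``.

Total branch length — the sum of all vertical connecting segments of a
dendrogram, with leaves at height 0 — serves as an indicator of
community-structure diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree as _scipy_cut_tree
from scipy.stats import norm

from .clustering import Dendrogram

__all__ = [
    "ContingencyCounts",
    "BkCurve",
    "cut_tree",
    "bk_statistic",
    "bk_null_moments",
    "bk_curve",
    "total_branch_length",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Cluster-overlap counts between two k-partitions and the derived
    pair-counting sums."""

    k: int
    m: np.ndarray
    n: int

    @property
    def T(self) -> float:
        return float((self.m.astype(np.int64) ** 2).sum() - self.n)

    @property
    def P(self) -> float:
        return float((self.m.sum(axis=1).astype(np.int64) ** 2).sum() - self.n)

    @property
    def Q(self) -> float:
        return float((self.m.sum(axis=0).astype(np.int64) ** 2).sum() - self.n)


@dataclass(frozen=True)
class BkCurve:
    ks: np.ndarray
    bk: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    rejection: np.ndarray
    alpha: float
    null_method: str

    def above_rejection(self) -> np.ndarray:
        return self.bk > self.rejection


def cut_tree(dend: Dendrogram, k: int) -> dict[str, int]:
    """Flat clustering from the ``k - 1`` highest merges of a dendrogram;
    exactly ``k`` non-empty clusters.  Height ties are resolved by merge
    order (the linkage ordering is authoritative)."""
    n = dend.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside the valid range 1..{n}")
    assignment = _scipy_cut_tree(dend.Z, n_clusters=k).ravel()
    return {lab: int(c) for lab, c in zip(dend.labels, assignment)}


def _contingency(c1: dict[str, int], c2: dict[str, int]) -> ContingencyCounts:
    if set(c1) != set(c2):
        raise ValueError("partitions are over different label sets")
    labels = sorted(c1)
    a = np.asarray([c1[x] for x in labels])
    b = np.asarray([c2[x] for x in labels])
    _, a = np.unique(a, return_inverse=True)
    _, b = np.unique(b, return_inverse=True)
    ka, kb = a.max() + 1, b.max() + 1
    k = max(ka, kb)
    m = np.zeros((k, k), dtype=np.int64)
    np.add.at(m, (a, b), 1)
    return ContingencyCounts(k, m, len(labels))


def bk_statistic(c1: dict[str, int], c2: dict[str, int]) -> float:
    """Fowlkes-Mallows pair-counting similarity between two flat
    partitions over the same labels; NaN when either partition consists
    entirely of singletons (no co-clustered pairs to compare)."""
    cc = _contingency(c1, c2)
    if cc.P == 0 or cc.Q == 0:
        return float("nan")
    return cc.T / np.sqrt(cc.P * cc.Q)


def bk_null_moments(sizes1: np.ndarray, sizes2: np.ndarray) -> tuple[float, float]:
    """Asymptotic mean and sd of ``B_k`` under random relabeling, given the
    marginal cluster sizes of the two partitions (Fowlkes-Mallows)."""
    sizes1 = np.asarray(sizes1, dtype=float)
    sizes2 = np.asarray(sizes2, dtype=float)
    n = sizes1.sum()
    if sizes2.sum() != n:
        raise ValueError("partitions cover different numbers of objects")
    P = float((sizes1**2).sum() - n)
    Q = float((sizes2**2).sum() - n)
    if P == 0 or Q == 0:
        return float("nan"), float("nan")
    Pp = float((sizes1 * (sizes1 - 1) * (sizes1 - 2)).sum())
    Qp = float((sizes2 * (sizes2 - 1) * (sizes2 - 2)).sum())
    mean = np.sqrt(P * Q) / (n * (n - 1))
    var = (
        2.0 / (n * (n - 1))
        + 4.0 * Pp * Qp / (n * (n - 1) * (n - 2) * P * Q)
        + (P - 2 - 4 * Pp / P) * (Q - 2 - 4 * Qp / Q)
        / (n * (n - 1) * (n - 2) * (n - 3))
        - P * Q / (n**2 * (n - 1) ** 2)
    )
    return float(mean), float(np.sqrt(max(var, 0.0)))


def _partition_sizes(c: dict[str, int]) -> np.ndarray:
    return np.bincount(np.unique(list(c.values()), return_inverse=True)[1])


def bk_curve(
    dend1: Dendrogram,
    dend2: Dendrogram,
    alpha: float = 0.05,
    null_method: str = "asymptotic",
    n_permutations: int = 999,
    seed: int = 0,
) -> BkCurve:
    """``B_k`` for every ``k = 2 .. n-1`` plus the one-sided rejection line
    at level ``alpha`` under the null of unrelated trees.

    ``null_method='asymptotic'`` uses the closed-form moments given the
    partitions' marginal cluster sizes; ``'permutation'`` estimates the
    same moments by relabeling the leaves of the second tree
    ``n_permutations`` times.
    """
    if set(dend1.labels) != set(dend2.labels):
        diff = set(dend1.labels) ^ set(dend2.labels)
        raise ValueError(f"trees have different leaf sets; symmetric "
                         f"difference: {sorted(diff)}")
    n = dend1.n_leaves
    if n < 4:
        raise ValueError("need at least 4 leaves for a non-trivial Bk curve")
    if null_method not in ("asymptotic", "permutation"):
        raise ValueError(f"unknown null method {null_method!r}")
    z = norm.ppf(1.0 - alpha)
    rng = np.random.default_rng(seed)
    ks = np.arange(2, n)
    bk = np.empty(ks.size)
    mean = np.empty(ks.size)
    sd = np.empty(ks.size)
    labels = list(dend1.labels)
    for i, k in enumerate(ks):
        c1 = cut_tree(dend1, int(k))
        c2 = cut_tree(dend2, int(k))
        bk[i] = bk_statistic(c1, c2)
        if null_method == "asymptotic":
            mean[i], sd[i] = bk_null_moments(_partition_sizes(c1),
                                             _partition_sizes(c2))
        else:
            vals2 = np.asarray([c2[x] for x in labels])
            sims = np.empty(n_permutations)
            for p in range(n_permutations):
                perm = rng.permutation(n)
                cp = {lab: int(v) for lab, v in zip(labels, vals2[perm])}
                sims[p] = bk_statistic(c1, cp)
            mean[i] = np.nanmean(sims)
            sd[i] = np.nanstd(sims)
    rejection = mean + z * sd
    return BkCurve(ks, bk, mean, sd, rejection, alpha, null_method)


def total_branch_length(dend: Dendrogram) -> float:
    """Sum of the vertical connecting-segment lengths of the dendrogram
    (leaves at height 0): each merge at height ``h`` contributes
    ``h - h_child`` for each of its two children."""
    n = dend.n_leaves
    heights = np.concatenate([np.zeros(n), dend.Z[:, 2]])
    total = 0.0
    for i, (a, b, h, _size) in enumerate(dend.Z):
        total += (h - heights[int(a)]) + (h - heights[int(b)])
    return float(total)
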