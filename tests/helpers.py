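"""Independent oracles used by the test suite.

Everything here is deliberately naive — brute-force pair enumeration,
exhaustive greedy search, direct rank counting — so it shares no code
path with the implementations it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from multinet.bipartite import TwoModeNetwork


def random_two_mode(rng: np.random.Generator, n_genes: int, n_cancers: int,
                    p: float = 0.3) -> TwoModeNetwork:
    """Random bipartite graph; nodes without edges are dropped."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    cancers = [f"c{i:02d}" for i in range(n_cancers)]
    mask = rng.random((n_genes, n_cancers)) < p
    edges = frozenset(
        (genes[i], cancers[j]) for i, j in zip(*np.nonzero(mask))
    )
    kept_g = tuple(g for g in genes if any(e[0] == g for e in edges))
    kept_c = tuple(c for c in cancers if any(e[1] == c for e in edges))
    return TwoModeNetwork(genes=kept_g, cancers=kept_c, edges=edges)


def brute_force_multiplicities(net: TwoModeNetwork, mode: str) -> dict[tuple[str, str], int]:
    """All-pairs shared-neighbor counts by direct set intersection."""
    if mode == "gene":
        nodes, neigh = net.genes, net.gene_cancer_sets
    else:
        nodes, neigh = net.cancers, net.cancer_gene_sets
    out = {}
    for a, b in combinations(sorted(nodes), 2):
        m = len(neigh[a] & neigh[b])
        if m:
            out[(a, b)] = m
    return out


def greedy_ward(points: np.ndarray):
    """Exhaustive greedy minimum-variance agglomeration.

    At each step every cluster pair is scored by the Ward merge cost
    (via the centroid closed form, reported on the square-root scale on
    which two singletons merge at their Euclidean distance) and the
    minimum is merged.  Returns (heights, cophenetic dict keyed by sorted
    leaf pair).
    """
    clusters = {i: [i] for i in range(len(points))}
    coph: dict[tuple[int, int], float] = {}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            na, nb = len(clusters[a]), len(clusters[b])
            ca = points[clusters[a]].mean(axis=0)
            cb = points[clusters[b]].mean(axis=0)
            d = np.sqrt(2.0 * na * nb / (na + nb)) * float(np.linalg.norm(ca - cb))
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[(min(i, j), max(i, j))] = d
        clusters[a] = clusters[a] + clusters.pop(b)
    return np.array(heights), coph


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic over positive/negative pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for s in pos:
        wins += (s > neg).sum() + 0.5 * (s == neg).sum()
    return wins / (len(pos) * len(neg))


def ecdf_ks_d(a: np.ndarray, b: np.ndarray) -> float:
    """sup_x (F_b - F_a) by sweeping every pooled point."""
    d = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, fb - fa)
    return d


def midrank_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rs by explicit midranking and Pearson on the ranks."""

    def midranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
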