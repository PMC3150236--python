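"""One-mode projections and multiplicity measures.

Projecting the bipartite cancer-gene graph onto one node class links two
same-mode nodes whenever they share at least one opposite-mode neighbor;
the integer link *multiplicity* is the number of shared neighbors (for two
genes, the number of cancers in which both are significantly mutated).  A
node's *maximum multiplicity* (the m-slice value) is the largest
multiplicity among its incident links — the score used throughout the
analysis to quantify systemic occurrence across cancers.

Cancer-cancer links can additionally be weighted so that each endpoint
contributes the inverse of its mutated-gene count, down-weighting cancers
that are linked to many genes simply because many genes are mutated in
them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import pandas as pd
from sklearn.base import BaseEstimator

from .bipartite import TwoModeNetwork

__all__ = [
    "OneModeNetwork",
    "OneModeProjector",
    "project_one_mode",
    "compute_max_multiplicity",
    "normalized_link_weight",
    "normalized_link_contributions",
    "all_normalized_weights",
    "write_one_mode",
    "write_node_table",
]


@dataclass(frozen=True)
class OneModeNetwork:
    """Same-mode graph with integer link multiplicities.

    ``links`` maps an ordered node pair ``(a, b)`` with ``a < b`` to its
    multiplicity; absent pairs have multiplicity zero.  ``shared`` holds the
    opposite-mode nodes behind each link.  ``max_multiplicity`` is filled by
    :func:`compute_max_multiplicity` (zero for isolated nodes).
    """

    mode: str
    nodes: tuple[str, ...]
    links: dict[tuple[str, str], int]
    shared: dict[tuple[str, str], frozenset[str]]
    max_multiplicity: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("gene", "cancer"):
            raise ValueError(f"mode must be 'gene' or 'cancer', got {self.mode!r}")
        for (a, b), m in self.links.items():
            if a >= b:
                raise ValueError(f"link key ({a!r}, {b!r}) must be ordered a < b")
            if m < 1:
                raise ValueError(f"stored link ({a!r}, {b!r}) has multiplicity {m} < 1")
            if m != len(self.shared[(a, b)]):
                raise ValueError(f"link ({a!r}, {b!r}): multiplicity != |shared set|")

    def multiplicity(self, a: str, b: str) -> int:
        if a == b:
            return 0
        key = (a, b) if a < b else (b, a)
        return self.links.get(key, 0)

    def neighbors(self, node: str) -> list[str]:
        out = []
        for a, b in self.links:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), m in self.links.items():
            g.add_edge(a, b, weight=m)
        return g


def project_one_mode(net: TwoModeNetwork, mode: str) -> OneModeNetwork:
    """Project the two-mode network onto ``mode`` ('gene' or 'cancer').

    Pairs are enumerated per opposite-mode node (over its deg-choose-2
    member pairs) rather than over all node pairs, so cost is
    O(sum of squared degrees).
    """
    if mode == "gene":
        nodes = net.genes
        groups = net.cancer_gene_sets
    elif mode == "cancer":
        nodes = net.cancers
        groups = net.gene_cancer_sets
    else:
        raise ValueError(f"mode must be 'gene' or 'cancer', got {mode!r}")

    shared: dict[tuple[str, str], set[str]] = {}
    for opposite, members in groups.items():
        for a, b in combinations(sorted(members), 2):
            shared.setdefault((a, b), set()).add(opposite)
    links = {pair: len(s) for pair, s in shared.items()}
    return OneModeNetwork(
        mode=mode,
        nodes=tuple(nodes),
        links=links,
        shared={pair: frozenset(s) for pair, s in shared.items()},
    )


def compute_max_multiplicity(net: OneModeNetwork) -> OneModeNetwork:
    """Fill each node's m-slice value: max incident link multiplicity.

    Isolated nodes get zero (no incident link).
    """
    values = {v: 0 for v in net.nodes}
    for (a, b), m in net.links.items():
        if m > values[a]:
            values[a] = m
        if m > values[b]:
            values[b] = m
    return replace(net, max_multiplicity=values)


class OneModeProjector(BaseEstimator):
    """Projection + m-slice as one estimator step.

    Attributes
    ----------
    network_ : OneModeNetwork
        Projection with ``max_multiplicity`` filled.
    """

    def __init__(self, mode: str = "gene"):
        self.mode = mode

    def fit(self, X: TwoModeNetwork, y=None) -> "OneModeProjector":
        self.network_ = compute_max_multiplicity(project_one_mode(X, self.mode))
        return self

    def transform(self, X: TwoModeNetwork) -> pd.Series:
        """Per-node maximum multiplicity of the fitted projection."""
        if not hasattr(self, "network_"):
            self.fit(X)
        mm = self.network_.max_multiplicity
        return pd.Series(mm, name="max_multiplicity").loc[list(self.network_.nodes)]


_COMBINE = ("mean", "sum", "min")


def normalized_link_contributions(
    net: TwoModeNetwork, pair: tuple[str, str]
) -> tuple[float, float]:
    """Endpoint contributions ``(1/||i||, 1/||j||)`` for a cancer pair.

    ``||i||`` is the number of mutated genes associated with cancer ``i``;
    a cancer linked to many genes contributes little to the link weight.
    """
    i, j = pair
    deg = net.cancer_gene_degree
    for c in (i, j):
        if deg.get(c, 0) == 0:
            raise ValueError(f"cancer {c!r} has no associated genes")
    return 1.0 / deg[i], 1.0 / deg[j]


def normalized_link_weight(
    net: TwoModeNetwork,
    one_mode: OneModeNetwork,
    pair: tuple[str, str],
    combine: str = "mean",
) -> float:
    """Mutation-rate-normalized weight of a cancer-cancer link.

    The default combines the endpoint contributions by their mean:
    ``weight = multiplicity * (1/||i|| + 1/||j||) / 2``.  ``combine`` may be
    ``mean``, ``sum`` or ``min``.
    """
    if one_mode.mode != "cancer":
        raise ValueError("normalized weights are defined on the cancer projection")
    if combine not in _COMBINE:
        raise ValueError(f"combine must be one of {_COMBINE}")
    i, j = pair
    m = one_mode.multiplicity(i, j)
    if m == 0:
        raise ValueError(f"no link between {i!r} and {j!r}")
    wi, wj = normalized_link_contributions(net, pair)
    if combine == "mean":
        factor = (wi + wj) / 2.0
    elif combine == "sum":
        factor = wi + wj
    else:
        factor = min(wi, wj)
    return m * factor


def all_normalized_weights(
    net: TwoModeNetwork, one_mode: OneModeNetwork, combine: str = "mean"
) -> dict[tuple[str, str], float]:
    """Normalized weight for every stored cancer-cancer link."""
    return {
        pair: normalized_link_weight(net, one_mode, pair, combine)
        for pair in one_mode.links
    }


def write_one_mode(net: OneModeNetwork, path: str | Path) -> None:
    """Weighted edge-list TSV with multiplicity as the edge value."""
    rows = [(a, b, m) for (a, b), m in sorted(net.links.items())]
    pd.DataFrame(rows, columns=[net.mode + "_a", net.mode + "_b", "multiplicity"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_table(net: OneModeNetwork, path: str | Path) -> None:
    """Per-node TSV with the maximum multiplicity value."""
    if net.max_multiplicity is None:
        net = compute_max_multiplicity(net)
    pd.Series(net.max_multiplicity, name="max_multiplicity").loc[
        list(net.nodes)
    ].rename_axis(net.mode).to_csv(path, sep="\t")


def write_pajek_one_mode(net: OneModeNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_pajek(net.to_networkx(), path)
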