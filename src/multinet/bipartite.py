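"""Significance-filtered two-mode cancer-gene network.

A gene is linked to a cancer type when its mutation rate in that type is
better than chance: the per-type mutant count is tested against the gene's
pooled rate across all retained types with a 1-df chi-square goodness-of-fit
test over the two cells {mutant, non-mutant}, and the edge is kept only when
the deviation is an enrichment (observed above expected) with p below alpha.
Pooling across types is the "chance" baseline: a gene mutated at the same
rate everywhere carries no type-specific signal and receives no edges.

No multiple-testing correction is applied by default (raw p < 0.05); a
Bonferroni option over the number of tested (gene, cancer) pairs is exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .catalog import MutationCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateBaselineError",
    "TwoModeNetwork",
    "chi_square_gof",
    "ChiSquareEdgeFilter",
    "build_two_mode",
    "write_edge_table",
    "write_pajek_two_mode",
]


class DegenerateBaselineError(ValueError):
    """Expected rate of 0 or 1 leaves a zero-count cell in expectation."""


def chi_square_gof(
    observed: int, n: int, expected_rate: float
) -> tuple[float, float, bool]:
    """1-df goodness-of-fit test of ``observed`` mutants among ``n`` tumors.

    The two cells are {mutant, non-mutant} with expected counts
    ``(n*r, n*(1-r))``.  Returns ``(statistic, p, enriched)`` where the p
    value is the chi-square(1) upper tail and ``enriched`` is True when the
    observed count exceeds expectation.
    """
    if not 0 <= observed <= n:
        raise ValueError(f"observed={observed} outside [0, n={n}]")
    if not 0.0 < expected_rate < 1.0:
        raise DegenerateBaselineError(
            f"expected_rate={expected_rate} must lie strictly inside (0, 1)"
        )
    expected = n * expected_rate
    dev = observed - expected
    statistic = dev * dev * (1.0 / expected + 1.0 / (n - expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p, bool(observed > expected)


@dataclass(frozen=True)
class TwoModeNetwork:
    """Bipartite gene-cancer graph with the surviving edges.

    Genes and cancers with no surviving edge are excluded from the node
    sets.  ``edge_table`` (optional) carries the per-edge test diagnostics.
    """

    genes: tuple[str, ...]
    cancers: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    edge_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        gset, cset = set(self.genes), set(self.cancers)
        for g, c in self.edges:
            if g not in gset or c not in cset:
                raise ValueError(f"edge ({g!r}, {c!r}) references unknown node")

    @cached_property
    def gene_cancer_sets(self) -> dict[str, frozenset[str]]:
        """Per gene, the set of cancers it is linked to."""
        out: dict[str, set[str]] = {g: set() for g in self.genes}
        for g, c in self.edges:
            out[g].add(c)
        return {g: frozenset(s) for g, s in out.items()}

    @cached_property
    def cancer_gene_sets(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {c: set() for c in self.cancers}
        for g, c in self.edges:
            out[c].add(g)
        return {c: frozenset(s) for c, s in out.items()}

    @cached_property
    def cancer_gene_degree(self) -> dict[str, int]:
        """``||i||``: number of mutated genes associated with cancer ``i``."""
        return {c: len(s) for c, s in self.cancer_gene_sets.items()}

    def biadjacency(self) -> pd.DataFrame:
        """Boolean gene x cancer incidence frame."""
        mat = pd.DataFrame(False, index=list(self.genes), columns=list(self.cancers))
        for g, c in self.edges:
            mat.loc[g, c] = True
        return mat


class ChiSquareEdgeFilter(BaseEstimator):
    """Builds the significance-filtered two-mode network from a catalog.

    Parameters
    ----------
    alpha : float, default 0.05
        Inclusion threshold on the per-edge p value.
    bonferroni : bool, default False
        Divide alpha by the number of tested (gene, cancer) pairs.

    Attributes
    ----------
    network_ : TwoModeNetwork
    edge_table_ : pandas.DataFrame
        One row per tested pair with observed, expected, statistic, p and
        the kept flag.
    n_tests_ : int
    """

    def __init__(self, alpha: float = 0.05, bonferroni: bool = False):
        self.alpha = alpha
        self.bonferroni = bonferroni

    def fit(self, X: MutationCatalog, y=None) -> "ChiSquareEdgeFilter":
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        catalog = X
        counts = catalog.counts.values.astype(float)
        n_c = catalog.samples_per_type.values.astype(float)
        total = float(catalog.total_samples)
        pooled = counts.sum(axis=1) / total

        ok = (pooled > 0.0) & (pooled < 1.0)
        n_skipped = int((~ok).sum())
        if n_skipped:
            logger.info("skipping %d genes with degenerate pooled rate", n_skipped)

        expected = pooled[:, None] * n_c[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = counts - expected
            statistic = dev**2 * (1.0 / expected + 1.0 / (n_c[None, :] - expected))
        statistic[~ok, :] = 0.0
        p = stats.chi2.sf(statistic, df=1)
        enriched = counts > expected

        tested = ok[:, None] & (counts > 0)
        self.n_tests_ = int(tested.sum())
        alpha_eff = self.alpha / self.n_tests_ if (self.bonferroni and self.n_tests_) else self.alpha
        keep = tested & enriched & (p < alpha_eff)

        gi, ci = np.nonzero(tested)
        genes = np.asarray(catalog.genes)
        cancers = np.asarray(catalog.cancer_types)
        table = pd.DataFrame(
            {
                "gene": genes[gi],
                "cancer": cancers[ci],
                "observed": counts[gi, ci].astype(int),
                "expected": expected[gi, ci],
                "statistic": statistic[gi, ci],
                "p": p[gi, ci],
                "kept": keep[gi, ci],
            }
        )
        edges = frozenset(
            (g, c) for g, c in zip(table.loc[table.kept, "gene"], table.loc[table.kept, "cancer"])
        )
        kept_genes = tuple(g for g in catalog.genes if any((g, c) in edges for c in catalog.cancer_types))
        kept_cancers = tuple(c for c in catalog.cancer_types if any((g, c) in edges for g in kept_genes))
        self.edge_table_ = table
        self.network_ = TwoModeNetwork(
            genes=kept_genes, cancers=kept_cancers, edges=edges,
            edge_table=table.loc[table.kept].reset_index(drop=True),
        )
        logger.info(
            "two-mode network: %d genes, %d cancers, %d edges (alpha=%g%s)",
            len(kept_genes), len(kept_cancers), len(edges), self.alpha,
            ", bonferroni" if self.bonferroni else "",
        )
        return self

    def transform(self, X: MutationCatalog) -> pd.DataFrame:
        """Return the boolean biadjacency frame of the fitted network."""
        if not hasattr(self, "network_"):
            self.fit(X)
        return self.network_.biadjacency()


def build_two_mode(
    catalog: MutationCatalog, alpha: float = 0.05, bonferroni: bool = False
) -> TwoModeNetwork:
    """Significance-filtered two-mode network (thin estimator wrapper)."""
    return ChiSquareEdgeFilter(alpha=alpha, bonferroni=bonferroni).fit(catalog).network_


def write_edge_table(net: TwoModeNetwork, path: str | Path) -> None:
    """Edge list TSV: gene, cancer, observed, expected, statistic, p."""
    if net.edge_table is not None:
        table = net.edge_table.drop(columns=["kept"], errors="ignore")
    else:
        table = pd.DataFrame(sorted(net.edges), columns=["gene", "cancer"])
    table.to_csv(path, sep="\t", index=False)


def write_pajek_two_mode(net: TwoModeNetwork, path: str | Path) -> None:
    """Bipartite Pajek .net file (via networkx) for interoperability."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.genes, bipartite="0")
    g.add_nodes_from(net.cancers, bipartite="1")
    g.add_edges_from(net.edges)
    nx.write_pajek(g, path)
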