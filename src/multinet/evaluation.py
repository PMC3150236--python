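"""Driver-gene evaluation: cluster scoring, ROC, and rank statistics.

Cluster-level prediction works by giving every gene its cluster's mean
score (mean maximum multiplicity, or mean mutation rate for the
rate-based measure) normalized by the largest cluster mean, then sweeping
that score against a causal-gene list to trace a ROC curve.  Four feature
spaces are compared: the full 3D embedding, maximum multiplicity alone,
the 2D layout alone, and mutation rate alone.

The statistical helpers cover the tests used alongside the networks: a
one-tailed two-sample Kolmogorov-Smirnov test (alternative: first sample
stochastically larger), Kruskal-Wallis with tie correction, and
Spearman/Pearson correlations with their t statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .catalog import MutationCatalog
from .clustering import ClusterAssignment, WardClustering, cut_tree
from .layout import Embedding3D
from .multiplicity import OneModeNetwork

__all__ = [
    "DegenerateScoreError",
    "EvaluationError",
    "MeasureSpec",
    "RocResult",
    "DEFAULT_MEASURES",
    "cluster_scores",
    "roc_auc",
    "compare_measures",
    "ks_two_sample_one_tailed",
    "kruskal_wallis",
    "spearman_rank",
    "pearson_corr",
]


class EvaluationError(ValueError):
    pass


class DegenerateScoreError(EvaluationError):
    """All cluster means are zero; normalized scores are undefined."""


@dataclass(frozen=True)
class MeasureSpec:
    """One clustering measure: a feature space plus its cluster count."""

    name: str  # kk_plus_multiplicity_3d | max_multiplicity_1d | kk_2d | mutation_rate_1d
    n_clusters: int

    _NAMES = ("kk_plus_multiplicity_3d", "max_multiplicity_1d", "kk_2d", "mutation_rate_1d")

    def __post_init__(self) -> None:
        if self.name not in self._NAMES:
            raise ValueError(f"unknown measure {self.name!r}")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")

    @property
    def dimension(self) -> str:
        return {"kk_plus_multiplicity_3d": "3D", "max_multiplicity_1d": "1D",
                "kk_2d": "2D", "mutation_rate_1d": "1D"}[self.name]


DEFAULT_MEASURES: tuple[MeasureSpec, ...] = (
    MeasureSpec("kk_plus_multiplicity_3d", 10),
    MeasureSpec("max_multiplicity_1d", 3),
    MeasureSpec("kk_2d", 9),
    MeasureSpec("mutation_rate_1d", 5),
)


@dataclass(frozen=True)
class RocResult:
    """ROC curve with trapezoidal AUC (ties follow the rank formulation)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be monotone")


def cluster_scores(
    assign: ClusterAssignment,
    node_values: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Per-gene normalized cluster score.

    Every gene inherits its cluster's mean value divided by the maximum
    cluster mean, so scores lie in (0, 1] with the top cluster at 1.
    """
    values = pd.Series(dict(node_values), dtype=float)
    means = values.loc[assign.labels.index].groupby(assign.labels).mean()
    top = means.max()
    if top <= 0:
        raise DegenerateScoreError("all cluster means are zero")
    return assign.labels.map(means / top).rename("score")


def roc_auc(scores: Mapping[str, float] | pd.Series, positives: Iterable[str]) -> RocResult:
    """ROC of per-gene scores against a positive (causal) gene set."""
    scores = pd.Series(dict(scores), dtype=float)
    pos = frozenset(positives)
    y = scores.index.isin(pos).astype(int)
    if y.sum() == 0:
        raise EvaluationError("no positive gene present among the scored genes")
    if y.sum() == len(y):
        raise EvaluationError("no negative gene present among the scored genes")
    fpr, tpr, thr = roc_curve(y, scores.values)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def _measure_features(
    spec: MeasureSpec,
    genes: Sequence[str],
    embedding: Embedding3D,
    max_multiplicity: pd.Series,
    rates: pd.Series,
) -> np.ndarray:
    frame = embedding.frame().loc[list(genes)]
    if spec.name == "kk_plus_multiplicity_3d":
        return frame[["x", "y", "z"]].values
    if spec.name == "kk_2d":
        return frame[["x", "y"]].values
    if spec.name == "max_multiplicity_1d":
        return max_multiplicity.loc[list(genes)].values.reshape(-1, 1).astype(float)
    return rates.loc[list(genes)].values.reshape(-1, 1)


def compare_measures(
    catalog: MutationCatalog,
    net: OneModeNetwork,
    embedding: Embedding3D,
    causal: Iterable[str],
    specs: Sequence[MeasureSpec] = DEFAULT_MEASURES,
) -> pd.DataFrame:
    """Cluster each measure's feature space and score it by ROC.

    Each measure is Ward-clustered into its own number of clusters, genes
    are scored by their normalized cluster mean (mean maximum multiplicity,
    or mean mutation rate for the rate measure), and the scores are swept
    against the causal list.  Returns a table with one row per measure:
    measure, dimension, n_clusters, auc.
    """
    if net.max_multiplicity is None:
        raise EvaluationError("projection lacks max multiplicity values")
    genes = list(embedding.nodes)
    mm = pd.Series(net.max_multiplicity, dtype=float)
    rates = catalog.mutation_rates()
    causal = frozenset(causal)

    rows = []
    for spec in specs:
        k = min(spec.n_clusters, len(genes))
        feats = _measure_features(spec, genes, embedding, mm, rates)
        if len(genes) < 2 or k == 1:
            labels = pd.Series(1, index=genes, name="cluster")
            assign = ClusterAssignment(cut_height=None, labels=labels)
        else:
            est = WardClustering(metric="euclidean").fit(feats, leaves=genes)
            assign = cut_tree(est.tree_, k=k)
        base = rates if spec.name == "mutation_rate_1d" else mm
        scores = cluster_scores(assign, base.loc[genes])
        result = roc_auc(scores, causal)
        rows.append(
            {
                "measure": spec.name,
                "dimension": spec.dimension,
                "n_clusters": assign.n_clusters,
                "auc": result.auc,
            }
        )
    return pd.DataFrame(rows)


def ks_two_sample_one_tailed(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """One-tailed two-sample KS test for "``a`` stochastically larger".

    D is the largest excess of b's empirical CDF over a's,
    ``D = sup_x (F_b(x) - F_a(x))``, and the asymptotic p value is
    ``exp(-2 m n D^2 / (m + n))``.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise EvaluationError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    f_a = np.searchsorted(a, grid, side="right") / m
    f_b = np.searchsorted(b, grid, side="right") / n
    d = float(max((f_b - f_a).max(), 0.0))
    p = float(min(1.0, math.exp(-2.0 * m * n * d * d / (m + n))))
    return d, p


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with its chi-square p value."""
    if len(groups) < 2:
        raise EvaluationError("need at least 2 groups")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def spearman_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Spearman rs with t = rs*sqrt((n-2)/(1-rs^2)) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise EvaluationError("need paired samples of length >= 3")
    rs = float(stats.spearmanr(x, y).statistic)
    if abs(rs) >= 1.0:
        return rs, math.inf if rs > 0 else -math.inf, 0.0
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rs, t, p


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson r with the analogous t statistic and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise EvaluationError("need paired samples of length >= 3")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return r, math.inf if r > 0 else -math.inf, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, t, p
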