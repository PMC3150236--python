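from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multinet.clustering import ClusterAssignment
from multinet.evaluation import (
    DEFAULT_MEASURES,
    DegenerateScoreError,
    EvaluationError,
    MeasureSpec,
    cluster_scores,
    compare_measures,
    kruskal_wallis,
    ks_two_sample_one_tailed,
    pearson_corr,
    roc_auc,
    spearman_rank,
)

from .helpers import ecdf_ks_d, mann_whitney_auc, midrank_spearman


def _assign(labels: dict[str, int]) -> ClusterAssignment:
    return ClusterAssignment(cut_height=None, labels=pd.Series(labels, name="cluster"))


class TestClusterScores:
    def test_top_cluster_scores_one_and_ratios_follow_means(self):
        assign = _assign({"a": 1, "b": 1, "c": 2, "d": 2})
        scores = cluster_scores(assign, {"a": 4, "b": 6, "c": 9, "d": 11})
        assert scores["c"] == scores["d"] == 1.0
        assert scores["a"] == pytest.approx(0.5)

    def test_single_cluster_gives_all_ones(self):
        assign = _assign({"a": 1, "b": 1})
        assert set(cluster_scores(assign, {"a": 2, "b": 4})) == {1.0}

    def test_all_zero_means_rejected(self):
        assign = _assign({"a": 1, "b": 2})
        with pytest.raises(DegenerateScoreError):
            cluster_scores(assign, {"a": 0.0, "b": 0.0})


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"p1": 0.9, "p2": 0.8, "n1": 0.2, "n2": 0.1}
        assert roc_auc(scores, {"p1", "p2"}).auc == 1.0

    def test_uninformative_constant_scores(self):
        scores = {f"g{i}": 0.5 for i in range(10)}
        assert roc_auc(scores, {"g0", "g1"}).auc == 0.5

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = {f"g{i}": float(v) for i, v in enumerate(rng.random(30))}
        res = roc_auc(scores, {f"g{i}" for i in range(10)})
        assert res.fpr[0] == res.tpr[0] == 0.0
        assert res.fpr[-1] == res.tpr[-1] == 1.0
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_equals_mann_whitney_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            named = {f"g{i}": s for i, s in enumerate(scores)}
            pos = {f"g{i}" for i in range(n) if labels[i] == 1}
            assert roc_auc(named, pos).auc == pytest.approx(mann_whitney_auc(scores, labels))

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(20)
        named = {f"g{i}": float(s) for i, s in enumerate(scores)}
        warped = {g: float(np.exp(3 * s)) for g, s in named.items()}
        pos = {f"g{i}" for i in range(7)}
        assert roc_auc(named, pos).auc == pytest.approx(roc_auc(warped, pos).auc)

    def test_empty_positive_or_negative_sets_rejected(self):
        scores = {"a": 1.0, "b": 0.5}
        with pytest.raises(EvaluationError):
            roc_auc(scores, set())
        with pytest.raises(EvaluationError):
            roc_auc(scores, {"a", "b"})


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        d, p = ks_two_sample_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_samples(self):
        d, p = ks_two_sample_one_tailed([2.0, 3.0, 4.0], [0.0, 1.0])
        assert d == 1.0

    def test_direction_one_sided(self):
        # first sample stochastically SMALLER: no CDF excess, D == 0
        d, _ = ks_two_sample_one_tailed([0.0, 1.0], [2.0, 3.0, 4.0])
        assert d == 0.0

    def test_statistic_matches_ecdf_sweep_and_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0.2, 1.0, size=int(rng.integers(5, 40)))
            b = rng.normal(0.0, 1.2, size=int(rng.integers(5, 40)))
            d, p = ks_two_sample_one_tailed(a, b)
            assert d == pytest.approx(ecdf_ks_d(a, b))
            assert d == pytest.approx(stats.ks_2samp(a, b, alternative="less").statistic)
            assert 0.0 <= p <= 1.0


class TestRankStatistics:
    def test_kruskal_needs_two_groups(self):
        with pytest.raises(EvaluationError):
            kruskal_wallis([[1.0, 2.0]])

    def test_kruskal_matches_scipy(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(loc, 1.0, size=20) for loc in (0.0, 0.3, 1.0)]
        h, p = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_spearman_perfect_monotone(self):
        rs, t, p = spearman_rank([1, 2, 3, 4], [10, 20, 30, 40])
        assert rs == 1.0 and t == np.inf

    def test_spearman_matches_midrank_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 6, size=12).astype(float)  # ties on purpose
            y = rng.integers(0, 6, size=12).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rs, t, p = spearman_rank(x, y)
            assert rs == pytest.approx(midrank_spearman(x, y))

    def test_spearman_t_formula(self):
        rng = np.random.default_rng(6)
        x = rng.random(10)
        y = x + rng.normal(0, 0.3, size=10)
        rs, t, p = spearman_rank(x, y)
        assert t == pytest.approx(rs * np.sqrt(8 / (1 - rs**2)))

    def test_pearson_matches_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.random(25)
        y = 2 * x + rng.normal(0, 0.4, size=25)
        r, t, p = pearson_corr(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


@pytest.fixture(scope="module")
def fitted(small_catalog):
    from multinet.pipeline import MultiplicityPipeline

    catalog, drivers = small_catalog
    pipe = MultiplicityPipeline(max_outer_iterations=1500, seed=0).fit(catalog, drivers)
    return catalog, drivers, pipe


class TestCompareMeasures:
    def test_reports_all_four_measures(self, fitted):
        catalog, drivers, pipe = fitted
        table = pipe.measure_table_
        assert list(table["measure"]) == [s.name for s in DEFAULT_MEASURES]
        assert ((table["auc"] >= 0.0) & (table["auc"] <= 1.0)).all()

    def test_one_cluster_run_is_uninformative(self, fitted):
        catalog, drivers, pipe = fitted
        specs = [MeasureSpec("max_multiplicity_1d", 1)]
        table = compare_measures(catalog, pipe.one_mode_, pipe.embedding_, drivers, specs)
        assert table["auc"].iloc[0] == 0.5

    def test_random_positives_are_uninformative_on_average(self, fitted):
        catalog, drivers, pipe = fitted
        rng = np.random.default_rng(8)
        genes = list(pipe.embedding_.nodes)
        specs = [MeasureSpec("max_multiplicity_1d", 3), MeasureSpec("mutation_rate_1d", 5)]
        aucs = []
        for _ in range(20):
            pos = set(rng.choice(genes, size=8, replace=False))
            table = compare_measures(catalog, pipe.one_mode_, pipe.embedding_, pos, specs)
            aucs.extend(table["auc"])
        assert 0.35 < float(np.mean(aucs)) < 0.65
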