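from __future__ import annotations

import itertools

import numpy as np
import pytest

from multinet.bipartite import TwoModeNetwork
from multinet.layout import (
    Embedding3D,
    KamadaKawaiEmbedding,
    LayoutConfig,
    assemble_3d,
    graph_distances,
    layout_energy,
)
from multinet.multiplicity import (
    OneModeNetwork,
    compute_max_multiplicity,
    project_one_mode,
)

from .helpers import random_two_mode


def _chain(mults: list[int]) -> OneModeNetwork:
    nodes = [f"n{i}" for i in range(len(mults) + 1)]
    links, shared = {}, {}
    for i, m in enumerate(mults):
        key = (nodes[i], nodes[i + 1])
        links[key] = m
        shared[key] = frozenset(f"x{i}{j}" for j in range(m))
    return OneModeNetwork(mode="gene", nodes=tuple(nodes), links=links, shared=shared)


class TestGraphDistances:
    def test_single_link_dissimilarity_is_inverse_multiplicity(self):
        nodes, d = graph_distances(_chain([2]))
        assert d[0, 1] == pytest.approx(0.5)

    def test_path_distances_add(self):
        nodes, d = graph_distances(_chain([1, 2]))
        i, j = nodes.index("n0"), nodes.index("n2")
        assert d[i, j] == pytest.approx(1.5)

    def test_unit_transform_counts_hops(self):
        nodes, d = graph_distances(_chain([1, 2]), transform="unit")
        assert d[nodes.index("n0"), nodes.index("n2")] == pytest.approx(2.0)

    def test_cross_component_distances_are_infinite(self):
        net = OneModeNetwork(
            mode="gene", nodes=("a", "b", "c"), links={("a", "b"): 1},
            shared={("a", "b"): frozenset({"x"})},
        )
        nodes, d = graph_distances(net)
        assert np.isinf(d[nodes.index("a"), nodes.index("c")])

    def test_matches_brute_force_relaxation(self):
        rng = np.random.default_rng(0)
        net = project_one_mode(random_two_mode(rng, 15, 8), "gene")
        nodes, d = graph_distances(net)
        # Floyd-Warshall by hand
        n = len(nodes)
        brute = np.full((n, n), np.inf)
        np.fill_diagonal(brute, 0.0)
        idx = {v: i for i, v in enumerate(nodes)}
        for (a, b), m in net.links.items():
            brute[idx[a], idx[b]] = brute[idx[b], idx[a]] = 1.0 / m
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    brute[i, j] = min(brute[i, j], brute[i, k] + brute[k, j])
        assert np.allclose(np.where(np.isinf(d), -1, d), np.where(np.isinf(brute), -1, brute))


class TestKamadaKawai:
    def test_two_nodes_rest_at_desired_edge_length(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        est = KamadaKawaiEmbedding(desired_edge_length=2.5, seed=0).fit(d)
        sep = np.linalg.norm(est.embedding_[0] - est.embedding_[1])
        assert sep == pytest.approx(2.5, abs=1e-3)

    def test_equilateral_triangle_recovered_within_one_percent(self):
        d = np.ones((3, 3))
        np.fill_diagonal(d, 0.0)
        p = KamadaKawaiEmbedding(seed=1).fit(d).embedding_
        seps = [np.linalg.norm(p[i] - p[j]) for i, j in itertools.combinations(range(3), 2)]
        assert max(seps) / min(seps) < 1.01

    def test_energy_trace_is_non_increasing(self, small_gene_net):
        nodes, d = graph_distances(small_gene_net)
        est = KamadaKawaiEmbedding(seed=0, max_outer_iterations=300).fit(d)
        for hist in est.energy_history_:
            assert np.all(np.diff(hist) <= 1e-9)

    def test_final_energy_competitive_with_generic_minimizer(self):
        """Independent check: scipy BFGS on the same energy from the same start."""
        from scipy.optimize import minimize
        from multinet.layout import _layout_component

        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        rng = np.random.default_rng(3)
        net = project_one_mode(random_two_mode(rng, 10, 5), "gene")
        nodes, dist = graph_distances(net)
        _, labels = connected_components(csr_matrix(np.isfinite(dist)), directed=False)
        comp = labels == np.bincount(labels).argmax()
        dist = dist[np.ix_(comp, comp)]
        n = len(dist)
        l = dist / dist.max()
        with np.errstate(divide="ignore"):
            k = 1.0 / dist**2
        np.fill_diagonal(k, 0.0)
        np.fill_diagonal(l, 0.0)

        est = KamadaKawaiEmbedding(seed=5).fit(dist)
        mine = layout_energy(est.embedding_[: n], l, k)

        def cost(flat):
            return layout_energy(flat.reshape(n, 2), l, k)

        rng2 = np.random.default_rng(5)
        x0 = rng2.normal(size=(n, 2)).ravel()
        ref = minimize(cost, x0, method="BFGS").fun
        assert mine <= ref * 1.10 + 1e-6

    def test_deterministic_under_link_insertion_order(self):
        rng = np.random.default_rng(4)
        net = project_one_mode(random_two_mode(rng, 9, 5), "gene")
        shuffled = OneModeNetwork(
            mode=net.mode, nodes=tuple(reversed(net.nodes)),
            links=dict(reversed(list(net.links.items()))),
            shared=net.shared,
        )
        n1, d1 = graph_distances(net)
        n2, d2 = graph_distances(shuffled)
        assert n1 == n2
        p1 = KamadaKawaiEmbedding(seed=9).fit(d1).embedding_
        p2 = KamadaKawaiEmbedding(seed=9).fit(d2).embedding_
        assert np.array_equal(p1, p2)

    def test_disconnected_components_are_packed_apart(self):
        d = np.full((4, 4), np.inf)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        p = KamadaKawaiEmbedding(seed=0).fit(d).embedding_
        within = np.linalg.norm(p[0] - p[1])
        across = min(np.linalg.norm(p[i] - p[j]) for i in (0, 1) for j in (2, 3))
        assert across > within


class TestAssemble3D:
    def _net_with_mm(self, mm: dict[str, int]) -> OneModeNetwork:
        nodes = tuple(sorted(mm))
        return OneModeNetwork(mode="gene", nodes=nodes, links={}, shared={},
                              max_multiplicity=dict(mm))

    def test_unit_cube_and_z_normalization(self):
        net = self._net_with_mm({"a": 1, "b": 23})
        xy = np.array([[0.0, 0.0], [3.0, 1.0]])
        emb = assemble_3d(xy, net.nodes, net)
        frame = emb.frame()
        assert frame.values.min() >= 0.0 and frame.values.max() <= 1.0
        assert frame.loc["a", "z"] == pytest.approx(1 / 23)
        assert frame.loc["b", "z"] == pytest.approx(1.0)

    def test_node_with_network_maximum_gets_z_one(self):
        net = self._net_with_mm({"a": 2, "b": 5, "c": 4})
        emb = assemble_3d(np.zeros((3, 2)), net.nodes, net)
        assert emb.frame().loc["b", "z"] == 1.0

    def test_degenerate_multiplicity_axis_centers_z(self):
        net = self._net_with_mm({"a": 3, "b": 3})
        emb = assemble_3d(np.array([[0.0, 0.0], [1.0, 0.5]]), net.nodes, net)
        assert set(emb.frame()["z"]) == {0.5}

    def test_quarter_turn_preserves_3d_distance_multiset(self):
        rng = np.random.default_rng(11)
        mm = {f"n{i}": int(v) for i, v in enumerate(rng.integers(1, 9, size=12))}
        net = self._net_with_mm(mm)
        xy = rng.normal(size=(12, 2))
        rot = xy @ np.array([[0.0, -1.0], [1.0, 0.0]])  # rigid 90-degree rotation
        e1 = assemble_3d(xy, net.nodes, net)
        e2 = assemble_3d(rot, net.nodes, net)
        from scipy.spatial.distance import pdist

        assert np.allclose(np.sort(pdist(e1.coords)), np.sort(pdist(e2.coords)))

    def test_z_scale_shrinks_the_multiplicity_axis(self):
        net = self._net_with_mm({"a": 1, "b": 4})
        emb = assemble_3d(np.array([[0.0, 0.0], [1.0, 0.0]]), net.nodes, net, z_scale=0.5)
        assert emb.frame()["z"].max() == pytest.approx(0.5)


def test_layout_config_validation():
    with pytest.raises(ValueError):
        LayoutConfig(desired_edge_length=0.0)
    with pytest.raises(ValueError):
        LayoutConfig(gradient_tolerance=-1.0)
    with pytest.raises(ValueError):
        LayoutConfig(distance_transform="nope")
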