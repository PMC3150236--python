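"""Kamada-Kawai layout and the 3D multiplicity embedding.

The 2D layout minimizes the spring energy

    E = sum_{i<j} (k_ij / 2) (||p_i - p_j|| - l_ij)^2

with rest lengths ``l_ij = L0 * d_ij / max(d)`` proportional to graph
distances and stiffness ``k_ij = K / d_ij^2``, following the classic
two-phase scheme: the outer loop repeatedly selects the node with the
largest gradient norm and the inner loop relaxes that node with a damped
2D Newton-Raphson until its gradient falls below tolerance.  Each accepted
move strictly decreases the energy (line search with step halving), so the
recorded energy trace is non-increasing.

Graph distances are weighted shortest paths with per-link dissimilarity
``1/multiplicity`` (high-multiplicity pairs sit close) or 1 for the unit
transform.  Disconnected components are laid out independently and packed
on a grid.  The third coordinate is the node's maximum multiplicity; all
coordinates are normalized into the unit cube (x, y jointly, preserving
aspect).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.base import BaseEstimator

from .multiplicity import OneModeNetwork, compute_max_multiplicity

logger = logging.getLogger(__name__)

__all__ = [
    "LayoutConfig",
    "Embedding3D",
    "graph_distances",
    "KamadaKawaiEmbedding",
    "kamada_kawai_layout",
    "assemble_3d",
    "layout_energy",
]

_TRANSFORMS = ("inverse_multiplicity", "unit")


@dataclass(frozen=True)
class LayoutConfig:
    """Spring-layout parameters.

    ``desired_edge_length`` (L0) sets the scale of the layout: the most
    distant pair in a component rests at separation L0.  ``spring_constant``
    (K) scales all stiffnesses and hence the energy, not the minimizer.
    ``gradient_tolerance`` is the per-node stopping threshold on the
    gradient norm; ``max_outer_iterations`` caps node relaxations (default
    40 per node).  The seed jitters the circular initialization.
    """

    desired_edge_length: float = 1.0
    spring_constant: float = 1.0
    gradient_tolerance: float = 1e-4
    max_outer_iterations: int | None = None
    seed: int = 0
    distance_transform: str = "inverse_multiplicity"

    def __post_init__(self) -> None:
        if self.desired_edge_length <= 0 or self.spring_constant <= 0:
            raise ValueError("desired_edge_length and spring_constant must be positive")
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient_tolerance must be positive")
        if self.max_outer_iterations is not None and self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be >= 1")
        if self.distance_transform not in _TRANSFORMS:
            raise ValueError(f"distance_transform must be one of {_TRANSFORMS}")


def graph_distances(
    net: OneModeNetwork,
    transform: str = "inverse_multiplicity",
    link_weights: dict[tuple[str, str], float] | None = None,
) -> tuple[tuple[str, ...], np.ndarray]:
    """All-pairs weighted shortest-path distances of the one-mode network.

    Per-link dissimilarity is ``1/multiplicity`` (or 1 under the ``unit``
    transform); when ``link_weights`` is supplied (e.g. normalized cancer
    link weights) the dissimilarity is ``1/weight``.  Node order is sorted;
    cross-component entries are ``inf``.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}")
    if not net.nodes:
        raise ValueError("network has no nodes")
    nodes = tuple(sorted(net.nodes))
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for (a, b), m in net.links.items():
        if link_weights is not None:
            delta = 1.0 / link_weights[(a, b)]
        elif transform == "unit":
            delta = 1.0
        else:
            delta = 1.0 / m
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [delta, delta]
    graph = csr_matrix((vals, (rows, cols)), shape=(n, n))
    dist = shortest_path(graph, method="D", directed=False)
    return nodes, dist


def layout_energy(pos: np.ndarray, l: np.ndarray, k: np.ndarray) -> float:
    """Total spring energy of a configuration."""
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(pos), k=1)
    return float((k[iu] / 2.0 * (d[iu] - l[iu]) ** 2).sum())


def _energy_and_gradients(
    pos: np.ndarray, l: np.ndarray, k: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """One vectorized pass: total energy, gradient norms, gradients."""
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 1.0)  # masked by k's zero diagonal
    coef = k * (1.0 - l / d)
    np.fill_diagonal(coef, 0.0)
    grads = np.einsum("ij,ijc->ic", coef, diff)
    iu = np.triu_indices(len(pos), k=1)
    energy = float((k[iu] / 2.0 * (d[iu] - l[iu]) ** 2).sum())
    return energy, np.hypot(grads[:, 0], grads[:, 1]), grads


def _terms_towards(m: int, pos: np.ndarray, l: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Each node's gradient contribution from its spring to node ``m``."""
    diff = pos - pos[m]
    d = np.sqrt((diff**2).sum(axis=1))
    d[m] = 1.0
    coef = k[:, m] * (1.0 - l[:, m] / d)
    coef[m] = 0.0
    return coef[:, None] * diff


def _node_gradient(m: int, pos: np.ndarray, l: np.ndarray, k: np.ndarray) -> np.ndarray:
    diff = pos[m] - pos
    d = np.sqrt((diff**2).sum(axis=1))
    d[m] = 1.0  # avoid 0/0; the m-th term is masked below
    coef = k[m] * (1.0 - l[m] / d)
    coef[m] = 0.0
    return coef @ diff


def _node_hessian(m: int, pos: np.ndarray, l: np.ndarray, k: np.ndarray) -> np.ndarray:
    diff = pos[m] - pos
    dx, dy = diff[:, 0], diff[:, 1]
    d = np.sqrt(dx**2 + dy**2)
    d[m] = 1.0
    d3 = d**3
    km = k[m].copy()
    km[m] = 0.0
    exx = float((km * (1.0 - l[m] * dy**2 / d3)).sum())
    eyy = float((km * (1.0 - l[m] * dx**2 / d3)).sum())
    exy = float((km * l[m] * dx * dy / d3).sum())
    return np.array([[exx, exy], [exy, eyy]])


def _node_energy(m: int, p_m: np.ndarray, pos: np.ndarray, l: np.ndarray, k: np.ndarray) -> float:
    diff = p_m - pos
    d = np.sqrt((diff**2).sum(axis=1))
    terms = k[m] / 2.0 * (d - l[m]) ** 2
    terms[m] = 0.0
    return float(terms.sum())


def _relax_node(
    m: int, pos: np.ndarray, l: np.ndarray, k: np.ndarray, tol: float, max_inner: int = 50
) -> None:
    """Newton-Raphson relaxation of node ``m`` in place, energy-guarded."""
    for _ in range(max_inner):
        g = _node_gradient(m, pos, l, k)
        if math.hypot(*g) < tol:
            return
        h = _node_hessian(m, pos, l, k)
        det = h[0, 0] * h[1, 1] - h[0, 1] * h[1, 0]
        if det > 1e-12 and h[0, 0] > 0:
            step = np.linalg.solve(h, -g)
        else:  # non-PD local Hessian: fall back to steepest descent
            step = -g
        e0 = _node_energy(m, pos[m], pos, l, k)
        t = 1.0
        while t > 1e-10:
            cand = pos[m] + t * step
            if _node_energy(m, cand, pos, l, k) < e0:
                pos[m] = cand
                break
            t *= 0.5
        else:
            return  # no descent direction left at this scale


def _layout_component(
    dist: np.ndarray, cfg: LayoutConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[float]]:
    """Lay out one connected component; returns positions and energy trace."""
    n = len(dist)
    if n == 1:
        return np.zeros((1, 2)), [0.0]
    dmax = dist[np.isfinite(dist)].max()
    if not np.isfinite(dist).all():
        raise ValueError("non-finite distance inside a component")
    l = cfg.desired_edge_length * dist / dmax
    with np.errstate(divide="ignore"):
        k = cfg.spring_constant / dist**2
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(l, 0.0)

    angles = 2.0 * np.pi * np.arange(n) / n
    angles = angles + rng.uniform(0.0, 2.0 * np.pi / n, size=n) * 0.25
    radius = l.max() / 2.0
    pos = radius * np.column_stack([np.cos(angles), np.sin(angles)])

    max_outer = cfg.max_outer_iterations or 40 * n
    energy, norms, grads = _energy_and_gradients(pos, l, k)
    energies = [energy]
    for it in range(max_outer):
        m = int(norms.argmax())
        if norms[m] < cfg.gradient_tolerance:
            break
        # moving node m changes only the (m, .) spring terms: update the
        # energy and the other nodes' gradients incrementally in O(n)
        e_before = _node_energy(m, pos[m], pos, l, k)
        old_terms = _terms_towards(m, pos, l, k)
        _relax_node(m, pos, l, k, cfg.gradient_tolerance)
        e_after = _node_energy(m, pos[m], pos, l, k)
        energy += e_after - e_before
        grads += _terms_towards(m, pos, l, k) - old_terms
        grads[m] = _node_gradient(m, pos, l, k)
        norms = np.hypot(grads[:, 0], grads[:, 1])
        if (it + 1) % 256 == 0:  # periodic full recompute against fp drift
            energy, norms, grads = _energy_and_gradients(pos, l, k)
        energies.append(energy)
    return pos, energies


class KamadaKawaiEmbedding(BaseEstimator):
    """Minimum-energy 2D embedding of a precomputed distance matrix.

    Mirrors the ``sklearn.manifold`` interface with precomputed
    dissimilarities: ``fit(X)`` expects a symmetric distance matrix whose
    ``inf`` entries mark cross-component pairs.  Components are laid out
    independently (rng streams keyed by seed and component rank, so results
    do not depend on input node order) and packed on a grid with a margin
    of one desired edge length.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, 2)
    energy_history_ : list of list of float
        Per-component energy trace, one value per outer iteration
        (non-increasing).
    n_iter_ : int
        Total outer iterations over all components.
    """

    def __init__(
        self,
        desired_edge_length: float = 1.0,
        spring_constant: float = 1.0,
        gradient_tolerance: float = 1e-4,
        max_outer_iterations: int | None = None,
        seed: int = 0,
    ):
        self.desired_edge_length = desired_edge_length
        self.spring_constant = spring_constant
        self.gradient_tolerance = gradient_tolerance
        self.max_outer_iterations = max_outer_iterations
        self.seed = seed

    def _config(self) -> LayoutConfig:
        return LayoutConfig(
            desired_edge_length=self.desired_edge_length,
            spring_constant=self.spring_constant,
            gradient_tolerance=self.gradient_tolerance,
            max_outer_iterations=self.max_outer_iterations,
            seed=self.seed,
        )

    def fit(self, X: np.ndarray, y=None) -> "KamadaKawaiEmbedding":
        cfg = self._config()
        dist = np.asarray(X, dtype=float)
        if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
            raise ValueError("X must be a square distance matrix")
        n = dist.shape[0]
        finite = np.isfinite(dist)
        n_comp, labels = connected_components(csr_matrix(finite), directed=False)

        pos = np.zeros((n, 2))
        histories: list[list[float]] = []
        boxes = []
        for comp in range(n_comp):
            members = np.nonzero(labels == comp)[0]
            sub = dist[np.ix_(members, members)]
            rng = np.random.default_rng([self.seed % (2**31), comp])
            p, hist = _layout_component(sub, cfg, rng)
            pos[members] = p
            histories.append(hist)
            lo, hi = p.min(axis=0), p.max(axis=0)
            boxes.append((members, lo, hi))

        if n_comp > 1:  # pack components on a grid with one-edge-length margin
            margin = cfg.desired_edge_length
            ncols = int(math.ceil(math.sqrt(n_comp)))
            cell_w = max(hi[0] - lo[0] for _, lo, hi in boxes) + margin
            cell_h = max(hi[1] - lo[1] for _, lo, hi in boxes) + margin
            for rank, (members, lo, _hi) in enumerate(boxes):
                r, c = divmod(rank, ncols)
                pos[members] += np.array([c * cell_w, r * cell_h]) - lo

        self.embedding_ = pos
        self.energy_history_ = histories
        self.n_iter_ = sum(len(h) - 1 for h in histories)
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def kamada_kawai_layout(
    distances: np.ndarray, cfg: LayoutConfig | None = None
) -> tuple[np.ndarray, list[list[float]]]:
    """Thin wrapper: 2D coordinates and per-component energy traces."""
    cfg = cfg or LayoutConfig()
    est = KamadaKawaiEmbedding(
        desired_edge_length=cfg.desired_edge_length,
        spring_constant=cfg.spring_constant,
        gradient_tolerance=cfg.gradient_tolerance,
        max_outer_iterations=cfg.max_outer_iterations,
        seed=cfg.seed,
    ).fit(distances)
    return est.embedding_, est.energy_history_


@dataclass(frozen=True)
class Embedding3D:
    """Unit-cube coordinates: (x, y) from the layout, z from multiplicity."""

    nodes: tuple[str, ...]
    coords: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.nodes), 3):
            raise ValueError("coords must be (n_nodes, 3)")
        if np.nanmin(self.coords) < -1e-9 or np.nanmax(self.coords) > 1.0 + 1e-9:
            raise ValueError("coordinates must lie in the unit cube")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=list(self.nodes), columns=["x", "y", "z"])

    def to_tsv(self, path) -> None:
        self.frame().rename_axis("node").to_csv(path, sep="\t")


def assemble_3d(
    layout: np.ndarray,
    nodes: tuple[str, ...],
    net: OneModeNetwork,
    z_scale: float = 1.0,
) -> Embedding3D:
    """Combine 2D layout with the multiplicity axis, normalized to [0,1].

    x and y are rescaled jointly (aspect preserved) into the unit square;
    z is max multiplicity over its network maximum, stretched by
    ``z_scale``.  A degenerate multiplicity axis (all values equal) is set
    to 0.5 everywhere and logged.
    """
    if net.max_multiplicity is None:
        net = compute_max_multiplicity(net)
    xy = np.asarray(layout, dtype=float)
    if xy.shape != (len(nodes), 2):
        raise ValueError("layout must cover all nodes with (x, y) rows")
    if not 0 < z_scale <= 1.0:
        raise ValueError("z_scale must lie in (0, 1]")

    lo = xy.min(axis=0)
    span = (xy.max(axis=0) - lo).max()
    if span > 0:
        xy = (xy - lo) / span
    else:
        xy = np.full_like(xy, 0.5)

    mm = np.array([net.max_multiplicity[v] for v in nodes], dtype=float)
    if mm.max() == mm.min():
        logger.info("degenerate multiplicity axis (all values %g): z set to 0.5", mm.max())
        z = np.full(len(nodes), 0.5)
    else:
        z = mm / mm.max() * z_scale
    return Embedding3D(nodes=tuple(nodes), coords=np.column_stack([xy, z]))
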