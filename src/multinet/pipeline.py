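"""End-to-end pipeline: catalog -> networks -> embedding -> clusters.

The six stages run in a fixed order — two-mode construction, one-mode
projection, multiplicity values, Kamada-Kawai plane, 3D distance matrix,
hierarchical clusters — for either the gene or the cancer mode.
``MultiplicityPipeline`` is the estimator form (fit a catalog, read the
fitted attributes); :func:`run_pipeline` is the artifact-writing form used
by the CLI, which records a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from . import __version__
from .bipartite import build_two_mode, write_edge_table, write_pajek_two_mode
from .catalog import MutationCatalog, equalize_samples, parse_catalog
from .clustering import (
    cluster_summary,
    cut_tree,
    euclidean_distances,
    to_newick,
    ward_cluster,
    write_merge_table,
)
from .evaluation import DEFAULT_MEASURES, MeasureSpec, compare_measures
from .fixtures import FixtureConfig, generate_catalog
from .layout import KamadaKawaiEmbedding, assemble_3d, graph_distances
from .multiplicity import (
    OneModeProjector,
    all_normalized_weights,
    write_node_table,
    write_one_mode,
)

logger = logging.getLogger(__name__)

__all__ = ["MultiplicityPipeline", "run_pipeline", "load_causal_list"]


def load_causal_list(path: str | Path) -> frozenset[str]:
    """Causal-gene list: one symbol per line, blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return frozenset(s.strip() for s in lines if s.strip())


class MultiplicityPipeline(BaseEstimator):
    """Catalog-to-clusters pipeline as a single estimator.

    Parameters mirror the stage options: the chi-square inclusion alpha,
    the projection mode, the multiplicity-to-distance transform, optional
    normalized cancer link weights, layout scale/tolerance, the z-axis
    stretch, the tree cut (height or count), and the seed for the layout
    initialization.

    Fitted attributes: ``two_mode_``, ``one_mode_``, ``distances_``,
    ``layout_``, ``embedding_``, ``tree_``, ``assignment_``, and
    ``measure_table_`` when a causal list is passed to :meth:`fit`.
    """

    def __init__(
        self,
        mode: str = "gene",
        alpha: float = 0.05,
        bonferroni: bool = False,
        distance_transform: str = "inverse_multiplicity",
        normalize_links: bool = False,
        combine: str = "mean",
        z_scale: float = 1.0,
        desired_edge_length: float = 1.0,
        gradient_tolerance: float = 1e-4,
        max_outer_iterations: int | None = None,
        cut_height: float | None = None,
        n_clusters: int | None = 10,
        seed: int = 0,
    ):
        self.mode = mode
        self.alpha = alpha
        self.bonferroni = bonferroni
        self.distance_transform = distance_transform
        self.normalize_links = normalize_links
        self.combine = combine
        self.z_scale = z_scale
        self.desired_edge_length = desired_edge_length
        self.gradient_tolerance = gradient_tolerance
        self.max_outer_iterations = max_outer_iterations
        self.cut_height = cut_height
        self.n_clusters = n_clusters
        self.seed = seed

    def fit(self, X: MutationCatalog, y: Iterable[str] | None = None):
        catalog = X
        causal = frozenset(y) if y is not None else None
        if self.normalize_links and self.mode != "cancer":
            raise ValueError("normalized link weights apply to the cancer mode")

        self.two_mode_ = build_two_mode(catalog, alpha=self.alpha, bonferroni=self.bonferroni)
        self.one_mode_ = OneModeProjector(mode=self.mode).fit(self.two_mode_).network_

        weights = None
        if self.normalize_links:
            weights = all_normalized_weights(self.two_mode_, self.one_mode_, self.combine)
        nodes, dist = graph_distances(
            self.one_mode_, transform=self.distance_transform, link_weights=weights
        )
        self.distances_ = dist
        kk = KamadaKawaiEmbedding(
            desired_edge_length=self.desired_edge_length,
            gradient_tolerance=self.gradient_tolerance,
            max_outer_iterations=self.max_outer_iterations,
            seed=self.seed,
        ).fit(dist)
        self.layout_ = kk
        self.embedding_ = assemble_3d(kk.embedding_, nodes, self.one_mode_, z_scale=self.z_scale)

        d3 = euclidean_distances(self.embedding_)
        self.tree_ = ward_cluster(d3, leaves=nodes)
        if self.cut_height is not None:
            assign = cut_tree(self.tree_, threshold=self.cut_height)
        else:
            k = min(self.n_clusters or 10, len(nodes))
            assign = cut_tree(self.tree_, k=k)
        mm = self.one_mode_.max_multiplicity
        self.assignment_ = cluster_summary(assign, mm, causal)

        if causal and self.mode == "gene":
            present = causal & set(nodes)
            if present and len(present) < len(nodes):
                self.measure_table_ = compare_measures(
                    catalog, self.one_mode_, self.embedding_, causal
                )
            else:
                self.measure_table_ = None
                logger.info("causal list does not split the network genes; ROC skipped")
        else:
            self.measure_table_ = None
        return self

    @property
    def labels_(self) -> np.ndarray:
        return self.assignment_.labels.values


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run all stages per a declarative config and write stage artifacts.

    Config keys (all optional unless noted): ``input`` (record TSV) or
    ``catalog_dir`` or ``simulate`` (fixture config mapping) as the data
    source; ``n_per_type``/``sample_seed`` for equalization; plus the
    :class:`MultiplicityPipeline` parameters and ``causal_list``.
    Artifacts: catalog dir, two-mode edge table + Pajek, one-mode edge
    list/node table, coordinates TSV, merge table + Newick + assignment,
    evaluation table, and ``manifest.json``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": cfg, "version": __version__, "stages": {}}

    # stage: catalog
    if "input" in cfg:
        records = parse_catalog(cfg["input"], cfg.get("dialect"))
        catalog = equalize_samples(
            records, n_per_type=int(cfg["n_per_type"]), seed=int(cfg.get("sample_seed", 0))
        )
        manifest["input_sha256"] = _sha256(Path(cfg["input"]))
    elif "catalog_dir" in cfg:
        catalog = MutationCatalog.from_dir(cfg["catalog_dir"])
    elif "simulate" in cfg:
        fix = FixtureConfig(**cfg["simulate"])
        catalog, drivers = generate_catalog(fix)
        (out / "truth.tsv").write_text(
            "gene\tis_driver\n"
            + "".join(f"{g}\t{g in drivers}\n" for g in catalog.genes)
        )
    else:
        raise ValueError("config needs one of: input, catalog_dir, simulate")
    catalog.to_dir(out / "catalog")
    manifest["stages"]["catalog"] = {
        "genes": len(catalog.genes),
        "cancer_types": len(catalog.cancer_types),
        "total_samples": catalog.total_samples,
    }

    causal = None
    if cfg.get("causal_list"):
        causal = load_causal_list(cfg["causal_list"])
    elif "simulate" in cfg:
        causal = drivers

    pipe_keys = {
        "mode", "alpha", "bonferroni", "distance_transform", "normalize_links",
        "combine", "z_scale", "desired_edge_length", "gradient_tolerance",
        "max_outer_iterations", "cut_height", "n_clusters", "seed",
    }
    pipe = MultiplicityPipeline(**{k: v for k, v in cfg.items() if k in pipe_keys})
    pipe.fit(catalog, causal)

    write_edge_table(pipe.two_mode_, out / "two_mode_edges.tsv")
    write_pajek_two_mode(pipe.two_mode_, out / "two_mode.net")
    manifest["stages"]["two_mode"] = {
        "genes": len(pipe.two_mode_.genes),
        "cancers": len(pipe.two_mode_.cancers),
        "edges": len(pipe.two_mode_.edges),
    }
    write_one_mode(pipe.one_mode_, out / "one_mode_links.tsv")
    write_node_table(pipe.one_mode_, out / "one_mode_nodes.tsv")
    manifest["stages"]["one_mode"] = {
        "nodes": len(pipe.one_mode_.nodes),
        "links": len(pipe.one_mode_.links),
        "max_multiplicity": int(max(pipe.one_mode_.max_multiplicity.values(), default=0)),
    }
    pipe.embedding_.to_tsv(out / "coordinates.tsv")
    write_merge_table(pipe.tree_, out / "merges.tsv")
    (out / "dendrogram.nwk").write_text(to_newick(pipe.tree_) + "\n")
    assign = pipe.assignment_
    assign.labels.rename_axis("node").to_csv(out / "clusters.tsv", sep="\t")
    assign.summary.to_csv(out / "cluster_summary.tsv", sep="\t")
    manifest["stages"]["clusters"] = {"n_clusters": assign.n_clusters}
    if assign.spearman is not None:
        rs, t, p = assign.spearman
        manifest["stages"]["clusters"]["spearman"] = {"rs": rs, "t": t, "p": p}
    if pipe.measure_table_ is not None:
        pipe.measure_table_.to_csv(out / "measure_comparison.tsv", sep="\t", index=False)
        manifest["stages"]["evaluation"] = {
            row["measure"]: row["auc"] for _, row in pipe.measure_table_.iterrows()
        }
    manifest["runtime_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete in %.1fs -> %s", manifest["runtime_s"], out)
    return out
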