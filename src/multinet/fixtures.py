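"""Synthetic mutation catalogs and toy networks with known ground truth.

The generator emulates the structure of a curated somatic-mutation
catalog under an equal-cohort design: a small set of *driver* genes is
mutated at a high rate in several cancers (systemic occurrence), a larger
set of *passenger* genes is mutated at a moderate rate in exactly one
cancer each, and everything else is low-rate background noise.  Per-sample
mutation flags are drawn independently (Bernoulli), so the per-type mutant
counts are binomial.  Ground-truth driver labels are returned so recovery
can be scored.

``figure1_toy`` freezes a minimal worked-example bipartite network: genes
a and b share exactly one cancer, genes c and d share exactly two, and
every gene's maximum link multiplicity is 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bipartite import TwoModeNetwork
from .catalog import MutationCatalog

__all__ = [
    "FixtureConfig",
    "generate_catalog",
    "write_fixture_tsv",
    "figure1_toy",
]


class FixtureConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    """Planted-structure catalog parameters.

    Defaults: 10 cancers of 500 tumors each; 20 drivers mutated at rate
    0.3 in 5 cancers apiece; 200 passengers mutated at rate 0.1 in one
    cancer each; background rate 0.01 everywhere else.
    """

    n_cancers: int = 10
    n_samples_per_cancer: int = 500
    n_driver_genes: int = 20
    n_passenger_genes: int = 200
    driver_breadth: int = 5
    driver_rate: float = 0.3
    passenger_rate: float = 0.1
    background_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_rate < 1.0):
            raise FixtureConfigError("background_rate must lie in [0, 1)")
        for name in ("driver_rate", "passenger_rate"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise FixtureConfigError(f"{name} must lie in (0, 1]")
        if self.driver_rate <= self.background_rate:
            raise FixtureConfigError("driver_rate must exceed background_rate")
        if not (1 <= self.driver_breadth <= self.n_cancers):
            raise FixtureConfigError("driver_breadth must lie in [1, n_cancers]")
        if min(self.n_cancers, self.n_samples_per_cancer, self.n_driver_genes) < 1:
            raise FixtureConfigError("counts must be positive")


def _gene_names(cfg: FixtureConfig) -> tuple[list[str], list[str]]:
    drivers = [f"DRV{i:03d}" for i in range(cfg.n_driver_genes)]
    passengers = [f"PSG{i:03d}" for i in range(cfg.n_passenger_genes)]
    return drivers, passengers


def _cancer_labels(cfg: FixtureConfig) -> list[str]:
    return [f"site{i:02d}|carcinoma" for i in range(cfg.n_cancers)]


def _rate_matrix(cfg: FixtureConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-(gene, cancer) Bernoulli rates under the planted structure."""
    drivers, passengers = _gene_names(cfg)
    cancers = _cancer_labels(cfg)
    rates = pd.DataFrame(cfg.background_rate, index=drivers + passengers,
                         columns=cancers, dtype=float)
    for g in drivers:
        chosen = rng.choice(cfg.n_cancers, size=cfg.driver_breadth, replace=False)
        rates.loc[g, [cancers[c] for c in chosen]] = cfg.driver_rate
    home = rng.integers(0, cfg.n_cancers, size=cfg.n_passenger_genes)
    for g, c in zip(passengers, home):
        rates.loc[g, cancers[c]] = cfg.passenger_rate
    return rates


def _draw_flags(cfg: FixtureConfig) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Rates plus per-cancer boolean (sample x gene) mutation flags."""
    rng = np.random.default_rng(cfg.seed)
    rates = _rate_matrix(cfg, rng)
    flags = {}
    for c in rates.columns:
        flags[c] = rng.random((cfg.n_samples_per_cancer, len(rates.index))) < rates[c].values
    return rates, flags


def generate_catalog(cfg: FixtureConfig) -> tuple[MutationCatalog, frozenset[str]]:
    """Draw a catalog under ``cfg`` and return it with the driver set."""
    rates, flags = _draw_flags(cfg)
    counts = pd.DataFrame(
        {c: f.sum(axis=0) for c, f in flags.items()}, index=rates.index
    ).astype(np.int64)
    keep = counts.sum(axis=1) > 0  # closed world: never-mutated genes are invisible
    counts = counts.loc[keep]
    samples = pd.Series(cfg.n_samples_per_cancer, index=list(rates.columns), name="n_samples")
    drivers, _ = _gene_names(cfg)
    catalog = MutationCatalog(counts=counts, samples_per_type=samples)
    return catalog, frozenset(drivers)


def write_fixture_tsv(
    cfg: FixtureConfig, path: str | Path, truth_path: str | Path | None = None
) -> None:
    """Write the fixture as a record-level TSV in the catalog dialect.

    Rows assert mutant (sample, gene) pairs only (closed world); parsing
    and aggregating the file reproduces :func:`generate_catalog`'s counts
    for the same config.  ``truth_path`` writes the driver labels sidecar.
    """
    rates, flags = _draw_flags(cfg)
    genes = np.asarray(rates.index)
    rows = []
    for c, mat in flags.items():
        site, histology = c.split("|")
        for s in range(mat.shape[0]):
            sample = f"{site}_s{s:04d}"
            for g in genes[mat[s]]:
                rows.append((sample, g, site, histology, "", "y"))
    frame = pd.DataFrame(
        rows,
        columns=["Sample_ID", "Gene_Name", "Site_Primary_COSMIC",
                 "Histology_COSMIC", "Histology_Subtype_COSMIC", "Mutated"],
    )
    frame.to_csv(path, sep="\t", index=False)
    if truth_path is not None:
        drivers, passengers = _gene_names(cfg)
        truth = pd.DataFrame(
            {"gene": drivers + passengers,
             "is_driver": [True] * len(drivers) + [False] * len(passengers)}
        )
        truth.to_csv(truth_path, sep="\t", index=False)


def figure1_toy() -> TwoModeNetwork:
    """Frozen worked-example bipartite network.

    Witness construction: genes a and b share only cancer B (link
    multiplicity 1), genes c and d share cancers A and C (multiplicity 2),
    and via gene d's broad associations every gene attains a maximum link
    multiplicity of exactly 2.
    """
    edges = frozenset(
        [
            ("a", "A"), ("a", "B"),
            ("b", "B"), ("b", "C"),
            ("c", "A"), ("c", "C"),
            ("d", "A"), ("d", "B"), ("d", "C"),
        ]
    )
    return TwoModeNetwork(genes=("a", "b", "c", "d"), cancers=("A", "B", "C"), edges=edges)
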