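from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from multinet import (
    FixtureConfig,
    MutationCatalog,
    OneModeProjector,
    build_two_mode,
    compute_max_multiplicity,
    generate_catalog,
    project_one_mode,
)
from multinet.fixtures import figure1_toy


@pytest.fixture(scope="session")
def toy():
    return figure1_toy()


@pytest.fixture(scope="session")
def toy_gene_net(toy):
    return compute_max_multiplicity(project_one_mode(toy, "gene"))


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down planted catalog for the layout-heavy tests."""
    return FixtureConfig(
        n_cancers=6, n_samples_per_cancer=200, n_driver_genes=8,
        n_passenger_genes=40, driver_breadth=3, seed=11,
    )


@pytest.fixture(scope="session")
def small_catalog(small_cfg):
    return generate_catalog(small_cfg)


@pytest.fixture(scope="session")
def small_gene_net(small_catalog):
    catalog, _ = small_catalog
    return OneModeProjector("gene").fit(build_two_mode(catalog)).network_


def counts_catalog(counts: dict[str, list[int]], genes: list[str], n: int) -> MutationCatalog:
    """Catalog from an explicit per-cancer count dict (equal cohorts)."""
    frame = pd.DataFrame(counts, index=genes)
    samples = pd.Series(n, index=frame.columns, name="n_samples")
    return MutationCatalog(counts=frame, samples_per_type=samples)
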