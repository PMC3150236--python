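"""Somatic-mutation catalogs.

A catalog is the count store feeding the whole analysis: for every derived
cancer type it records how many of the sampled tumors carry a mutation in
each gene.  The representation is deliberately closed-world — a mutation
exists if and only if a record asserts it — so per-gene denominators are the
full per-type sample counts, never a "tested" subset.

Cancer-type labels are derived from the anatomic site and histology fields:
epithelial and soft-tissue tumors are labelled ``site|histology``; blood
(haematopoietic/lymphoid) tumors and CNS gliomas are labelled by their
histological subtype, which carries the clinically meaningful distinction
for those tissues.

Cohorts are equalized by drawing the same number of tumors per cancer type
without replacement, dropping types with too few samples; unequal cohort
sizes would otherwise let large cohorts dominate every downstream distance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CatalogError",
    "FormatError",
    "EmptyInputError",
    "ClassificationError",
    "EmptyCatalogError",
    "MutationRecord",
    "TissueClass",
    "CancerTypeRule",
    "DEFAULT_RULES",
    "DEFAULT_DIALECT",
    "MutationCatalog",
    "parse_catalog",
    "derive_cancer_type",
    "build_catalog",
    "equalize_samples",
    "gene_mutation_rate",
]


class CatalogError(ValueError):
    """Base class for catalog-layer errors."""


class FormatError(CatalogError):
    """Input table does not expose a mandatory column."""


class EmptyInputError(CatalogError):
    """Input file contains no usable rows."""


class ClassificationError(CatalogError):
    """A record cannot be mapped to a cancer-type label."""


class EmptyCatalogError(CatalogError):
    """No cancer type survives sample-size equalization."""


@dataclass(frozen=True)
class MutationRecord:
    """One observation: a tumor sample assayed for a gene.

    ``is_mutant`` is True when any substitution, insertion or deletion was
    recorded for the gene in that sample; all mutation classes are collapsed
    to a single gene-level flag.
    """

    sample_id: str
    gene: str
    site_primary: str
    histology: str
    histology_subtype: str = ""
    is_mutant: bool = True

    def __post_init__(self) -> None:
        if not self.sample_id or not self.gene:
            raise FormatError("sample_id and gene must be non-empty")


class TissueClass(str, Enum):
    EPITHELIAL_OR_SOFT_TISSUE = "epithelial_or_soft_tissue"
    HEMATOPOIETIC_LYMPHOID = "hematopoietic_lymphoid"
    CNS_GLIOMA = "cns_glioma"
    OTHER = "other"


def _norm(s: str) -> str:
    return s.strip().lower().replace(" ", "_")


@dataclass(frozen=True)
class CancerTypeRule:
    """Maps a record to a cancer-type label.

    A rule matches when any of ``site_keywords`` occurs in the normalized
    anatomic site (and, if given, any of ``histology_keywords`` in the
    normalized histology).  Matching rules with ``use_subtype`` label by the
    histological subtype; otherwise the label concatenates site and
    histology as ``site|histology``.  An empty keyword tuple matches
    everything (catch-all).
    """

    tissue_class: TissueClass
    site_keywords: tuple[str, ...] = ()
    histology_keywords: tuple[str, ...] = ()
    use_subtype: bool = False
    subtype_required: bool = False

    def matches(self, record: MutationRecord) -> bool:
        site = _norm(record.site_primary)
        if self.site_keywords and not any(k in site for k in self.site_keywords):
            return False
        if self.histology_keywords:
            hist = _norm(record.histology)
            if not any(k in hist for k in self.histology_keywords):
                return False
        return True

    def label(self, record: MutationRecord) -> str:
        subtype = record.histology_subtype.strip()
        if self.use_subtype:
            if subtype:
                return subtype
            if self.subtype_required:
                raise ClassificationError(
                    f"record {record.sample_id!r}/{record.gene!r}: "
                    f"{self.tissue_class.value} tissue requires a histology subtype"
                )
        return f"{record.site_primary.strip()}|{record.histology.strip()}"


DEFAULT_RULES: tuple[CancerTypeRule, ...] = (
    CancerTypeRule(
        TissueClass.HEMATOPOIETIC_LYMPHOID,
        site_keywords=("haematopoietic", "hematopoietic", "lymphoid"),
        use_subtype=True,
        subtype_required=True,
    ),
    CancerTypeRule(
        TissueClass.CNS_GLIOMA,
        site_keywords=("central_nervous_system",),
        histology_keywords=("glioma",),
        use_subtype=True,
    ),
    CancerTypeRule(TissueClass.EPITHELIAL_OR_SOFT_TISSUE),
)


def derive_cancer_type(
    record: MutationRecord,
    rules: Sequence[CancerTypeRule] = DEFAULT_RULES,
) -> str:
    """Return the derived cancer-type label for ``record``.

    The first matching rule wins; the default rule set ends in a catch-all,
    so every record maps to exactly one label.
    """
    for rule in rules:
        if rule.matches(record):
            return rule.label(record)
    raise ClassificationError(
        f"no rule matches record {record.sample_id!r} (site={record.site_primary!r})"
    )


DEFAULT_DIALECT: Mapping[str, str] = {
    "sample_id": "Sample_ID",
    "gene": "Gene_Name",
    "site_primary": "Site_Primary_COSMIC",
    "histology": "Histology_COSMIC",
    "histology_subtype": "Histology_Subtype_COSMIC",
    "is_mutant": "Mutated",
}

_MANDATORY = ("sample_id", "gene", "site_primary", "histology")
_TRUTHY = {"y", "yes", "true", "t", "1"}
_FALSY = {"n", "no", "false", "f", "0", ""}


def _parse_flag(value: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise FormatError(f"unparsable mutation flag {value!r}")


def parse_catalog(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Parse a tab-separated mutation table into de-duplicated records.

    ``dialect`` maps logical field names to the file's column names and
    defaults to the COSMIC-style export headers.  Unknown extra columns are
    ignored.  Duplicate (sample, gene) rows collapse by logical OR of the
    mutant flag.  The subtype and flag columns are optional: absent subtype
    means empty, absent flag means mutated (rows assert mutations under the
    closed world).
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if frame.empty:
        raise EmptyInputError(f"{path}: no data rows")
    for key in _MANDATORY:
        if cols[key] not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {cols[key]!r}")

    has_subtype = cols["histology_subtype"] in frame.columns
    has_flag = cols["is_mutant"] in frame.columns

    records: dict[tuple[str, str], MutationRecord] = {}
    rejected = 0
    for row in frame.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(frame.columns, row))
        sample = str(r[cols["sample_id"]]).strip()
        gene = str(r[cols["gene"]]).strip()
        if not sample or not gene:
            rejected += 1
            continue
        rec = MutationRecord(
            sample_id=sample,
            gene=gene,
            site_primary=str(r[cols["site_primary"]]),
            histology=str(r[cols["histology"]]),
            histology_subtype=str(r[cols["histology_subtype"]]) if has_subtype else "",
            is_mutant=_parse_flag(str(r[cols["is_mutant"]])) if has_flag else True,
        )
        key = (sample, gene)
        prev = records.get(key)
        if prev is None:
            records[key] = rec
        elif rec.is_mutant and not prev.is_mutant:
            records[key] = rec
    logger.info(
        "parsed %s: %d rows, %d records, %d rejected",
        path, len(frame), len(records), rejected,
    )
    return list(records.values())


@dataclass
class MutationCatalog:
    """Closed-world mutant-sample counts per (gene, cancer type).

    ``counts`` is an integer matrix indexed by gene (rows) and cancer type
    (columns); ``samples_per_type`` holds the number of sampled tumors per
    type (equal across types after equalization).
    """

    counts: pd.DataFrame
    samples_per_type: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.samples_per_type = self.samples_per_type.astype(np.int64)
        self.validate()

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.samples_per_type.index):
            raise CatalogError("counts columns and samples_per_type index disagree")
        if (self.counts.values < 0).any():
            raise CatalogError("negative mutant count")
        over = self.counts.gt(self.samples_per_type, axis=1)
        if over.values.any():
            raise CatalogError("mutant count exceeds sampled tumors for its type")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cancer_types(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_samples(self) -> int:
        return int(self.samples_per_type.sum())

    @property
    def n_per_type(self) -> int:
        sizes = self.samples_per_type.unique()
        if len(sizes) != 1:
            raise CatalogError("cohort sizes are not equalized")
        return int(sizes[0])

    def mutation_rate(self, gene: str) -> float:
        """Fraction of all sampled tumors mutant in ``gene``."""
        if gene not in self.counts.index:
            raise KeyError(f"unknown gene {gene!r}")
        return float(self.counts.loc[gene].sum()) / self.total_samples

    def mutation_rates(self) -> pd.Series:
        return self.counts.sum(axis=1) / self.total_samples

    # -- serialization ----------------------------------------------------

    def to_dir(self, out_dir: str | Path, manifest: dict | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
        self.samples_per_type.rename("n_samples").rename_axis("cancer_type").to_csv(
            out / "samples.tsv", sep="\t"
        )
        if manifest is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "MutationCatalog":
        src = Path(in_dir)
        counts = pd.read_csv(src / "counts.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(src / "samples.tsv", sep="\t", index_col=0)["n_samples"]
        return cls(counts=counts, samples_per_type=samples)


def build_catalog(
    records: Iterable[MutationRecord],
    rules: Sequence[CancerTypeRule] = DEFAULT_RULES,
) -> MutationCatalog:
    """Aggregate records into a catalog without sample equalization.

    Cohort sizes are the observed distinct-sample counts per derived type;
    use :func:`equalize_samples` for the equal-size study design.
    """
    records = list(records)
    if not records:
        raise EmptyCatalogError("no records")
    labels = [derive_cancer_type(r, rules) for r in records]
    samples: dict[str, set[str]] = {}
    counts: dict[tuple[str, str], int] = {}
    for rec, label in zip(records, labels):
        samples.setdefault(label, set()).add(rec.sample_id)
        if rec.is_mutant:
            counts[(rec.gene, label)] = counts.get((rec.gene, label), 0) + 1
    types = sorted(samples)
    genes = sorted({g for g, _ in counts})
    mat = pd.DataFrame(0, index=genes, columns=types, dtype=np.int64)
    for (g, c), v in counts.items():
        mat.loc[g, c] = v
    per_type = pd.Series({c: len(samples[c]) for c in types}, name="n_samples")
    return MutationCatalog(counts=mat, samples_per_type=per_type.loc[types])


def equalize_samples(
    records: Iterable[MutationRecord],
    n_per_type: int,
    seed: int,
    rules: Sequence[CancerTypeRule] = DEFAULT_RULES,
) -> MutationCatalog:
    """Draw equal-size cohorts per cancer type and recount mutations.

    Cancer types with fewer than ``n_per_type`` distinct tumors are dropped
    (logged); for the survivors exactly ``n_per_type`` tumors are drawn
    without replacement.  The sampling unit is the tumor: a drawn tumor
    carries all its gene flags.  Candidate sample IDs are sorted before the
    seeded draw so the result is independent of input row order.
    """
    if n_per_type < 1:
        raise CatalogError("n_per_type must be >= 1")
    records = list(records)
    if not records:
        raise EmptyCatalogError("no records")
    labels = [derive_cancer_type(r, rules) for r in records]
    by_type: dict[str, set[str]] = {}
    for rec, label in zip(records, labels):
        by_type.setdefault(label, set()).add(rec.sample_id)

    retained = sorted(c for c, s in by_type.items() if len(s) >= n_per_type)
    dropped = sorted(set(by_type) - set(retained))
    if dropped:
        logger.info("dropping %d cancer types below %d samples: %s",
                    len(dropped), n_per_type, dropped)
    if not retained:
        raise EmptyCatalogError(
            f"no cancer type has {n_per_type} or more distinct samples"
        )

    rng = np.random.default_rng(seed)
    kept: dict[str, frozenset[str]] = {}
    for label in retained:
        candidates = sorted(by_type[label])
        chosen = rng.choice(len(candidates), size=n_per_type, replace=False)
        kept[label] = frozenset(candidates[i] for i in chosen)

    counts: dict[tuple[str, str], int] = {}
    for rec, label in zip(records, labels):
        if label in kept and rec.sample_id in kept[label] and rec.is_mutant:
            counts[(rec.gene, label)] = counts.get((rec.gene, label), 0) + 1
    genes = sorted({g for g, _ in counts})
    if not genes:
        raise EmptyCatalogError("no mutant gene among retained samples")
    mat = pd.DataFrame(0, index=genes, columns=retained, dtype=np.int64)
    for (g, c), v in counts.items():
        mat.loc[g, c] = v
    per_type = pd.Series(n_per_type, index=retained, name="n_samples")
    return MutationCatalog(counts=mat, samples_per_type=per_type)


def gene_mutation_rate(catalog: MutationCatalog, gene: str) -> float:
    """Overall mutation rate of ``gene``: mutant tumors / all sampled tumors."""
    return catalog.mutation_rate(gene)
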