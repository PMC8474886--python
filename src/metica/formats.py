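"""Readers, writers and core table containers.

Every table the pipeline touches is plain tab-separated text (expression,
weight, activity and response matrices), GMT (gene sets) or JSON (the
compendium manifest).  Readers validate and reject malformed input rather
than silently coercing it; every writer produces files its reader accepts.

Gene identifiers are opaque strings matched exactly (case-sensitive): the
pipeline operates downstream of platform mapping and performs no aliasing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "CompendiumManifest",
    "GmtParseError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_manifest",
    "write_manifest",
    "summarize_manifest",
    "published_compendium_manifest",
]


class GmtParseError(ValueError):
    """Raised for a malformed GMT line (fewer than 3 tab-separated fields)."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a dataset label.

    ``values`` is indexed by unique gene identifiers (rows) and unique
    sample identifiers (columns); every entry must be finite.  After
    preprocessing (see :func:`read_expression`) every retained gene has
    nonzero variance, which the independent-component decomposition
    requires.
    """

    values: pd.DataFrame
    dataset_label: str

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:10]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:10]}")
        if self.values.size == 0:
            raise ValueError("expression matrix has zero genes or zero samples")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional per-set collection label.

    Set names are unique, every set is non-empty, and duplicate genes
    within a set have been removed (first occurrence kept).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    collection_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                # Containers are always constructed deduplicated; readers
                # dedup with a warning before reaching this point.
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# --------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, dataset_label: str) -> ExpressionMatrix:
    """Read a tab-separated genes x samples table.

    The first column holds gene identifiers, the header row sample
    identifiers.  Gene rows containing any non-finite value are dropped
    (count logged), as are zero-variance genes.  Ragged rows and duplicate
    gene identifiers raise.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty expression file")
    n_fields = lines[0].count("\t") + 1
    for i, line in enumerate(lines):
        if line.count("\t") + 1 != n_fields:
            raise ValueError(
                f"{path}: ragged row at line {i + 1} "
                f"({line.count(chr(9)) + 1} fields, expected {n_fields})"
            )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs: {dups}")
    df = df.apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(df.to_numpy()).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("%s: dropped %d gene rows with non-finite values", path, n_dropped)
        df = df.loc[finite]
    variances = df.to_numpy().var(axis=1)
    n_const = int((variances == 0).sum())
    if n_const:
        logger.info("%s: dropped %d zero-variance gene rows", path, n_const)
        df = df.loc[variances != 0]
    return ExpressionMatrix(values=df, dataset_label=dataset_label)


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")


# --------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, collection_label: str | None = None) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes.

    Duplicate member genes are deduplicated with a logged warning; a line
    with fewer than three fields raises :class:`GmtParseError` naming the
    line number.  An empty file yields an empty collection with a warning.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        logger.warning("%s: empty GMT file, returning empty collection", path)
        return GeneSetCollection(sets={})
    for i, line in enumerate(lines):
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"{path}: line {i + 1} has {len(fields)} fields, expected >= 3"
            )
        name, desc, genes = fields[0], fields[1], fields[2:]
        genes = [g for g in genes if g != ""]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            logger.warning(
                "%s: set %s has %d duplicate member genes, deduplicated",
                path, name, len(genes) - len(deduped),
            )
        if name in sets:
            raise GmtParseError(f"{path}: duplicate set name {name!r} at line {i + 1}")
        sets[name] = deduped
        descriptions[name] = desc
        if collection_label is not None:
            labels[name] = collection_label
    return GeneSetCollection(sets=sets, descriptions=descriptions, collection_labels=labels)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# --------------------------------------------------------------------------
# compendium manifest


@dataclass
class CompendiumManifest:
    """Bookkeeping counts for a multi-dataset compendium.

    ``samples_per_dataset`` maps dataset name to sample count,
    ``gene_sets_per_collection`` maps gene-set catalogue name to set count,
    ``sample_class_counts`` maps sample class (cancer biopsy, non-cancer
    tissue, cell line) to count, and ``cell_line_datasets`` names the
    datasets whose samples are cell lines.
    """

    samples_per_dataset: dict[str, int]
    gene_sets_per_collection: dict[str, int] = field(default_factory=dict)
    sample_class_counts: dict[str, int] = field(default_factory=dict)
    cell_line_datasets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mapping in (self.samples_per_dataset, self.gene_sets_per_collection,
                        self.sample_class_counts):
            for key, count in mapping.items():
                if not (isinstance(count, (int, np.integer)) and count >= 0):
                    raise ValueError(f"manifest count for {key!r} must be a non-negative integer")


def summarize_manifest(manifest: CompendiumManifest) -> dict[str, int]:
    """Return total samples, total gene sets and total cell-line samples."""
    total_samples = sum(manifest.samples_per_dataset.values())
    total_gene_sets = sum(manifest.gene_sets_per_collection.values())
    total_cell_lines = sum(
        manifest.samples_per_dataset.get(d, 0) for d in manifest.cell_line_datasets
    )
    return {
        "total_samples": int(total_samples),
        "total_gene_sets": int(total_gene_sets),
        "total_cell_line_samples": int(total_cell_lines),
    }


def published_compendium_manifest() -> CompendiumManifest:
    """The four-compendium census of the published metabolic landscape.

    Sample counts for the GEO, TCGA, CCLE and GDSC collections and the
    per-catalogue counts of the curated metabolic gene sets (MSigDB v6.1
    selections), used as an arithmetic consistency fixture.
    """
    return CompendiumManifest(
        samples_per_dataset={"GEO": 21592, "TCGA": 10817, "CCLE": 1067, "GDSC": 1018},
        gene_sets_per_collection={"BioCarta": 7, "KEGG": 64, "GO": 508, "Reactome": 29},
        sample_class_counts={
            "cancer_biopsy": 28200,
            "non_cancer_tissue": 4209,
            "cell_line": 2085,
        },
        cell_line_datasets=["CCLE", "GDSC"],
    )


def read_manifest(path: str | Path) -> CompendiumManifest:
    with open(path) as fh:
        payload = json.load(fh)
    return CompendiumManifest(
        samples_per_dataset=dict(payload.get("samples_per_dataset", {})),
        gene_sets_per_collection=dict(payload.get("gene_sets_per_collection", {})),
        sample_class_counts=dict(payload.get("sample_class_counts", {})),
        cell_line_datasets=list(payload.get("cell_line_datasets", [])),
    )


def write_manifest(manifest: CompendiumManifest, path: str | Path) -> None:
    payload = {
        "samples_per_dataset": manifest.samples_per_dataset,
        "gene_sets_per_collection": manifest.gene_sets_per_collection,
        "sample_class_counts": manifest.sample_class_counts,
        "cell_line_datasets": manifest.cell_line_datasets,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
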