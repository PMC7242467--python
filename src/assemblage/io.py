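"""Readers and writers for the plain-text interchange formats.

All tables are UTF-8 tab-separated files with a header row; the OTU table
has sample ids in the first column and OTU ids as the remaining headers.
Trees are newick with branch lengths. Writers and readers round-trip
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .core import OtuTable, Phylogeny, SampleMetadata, Taxonomy


@dataclass
class InputBundle:
    """Validated, cross-referenced set of pipeline inputs."""

    table: OtuTable
    phylogeny: Phylogeny
    metadata: SampleMetadata
    taxonomy: Taxonomy | None = None


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})


def read_otu_table(path: str | Path) -> OtuTable:
    return OtuTable(_read_tsv(path))


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path))


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> Taxonomy:
    return Taxonomy(_read_tsv(path))


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    taxonomy.data.to_csv(path, sep="\t", index_label="otu_id")


def read_tree(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path))


def write_tree(phylogeny: Phylogeny, path: str | Path) -> None:
    phylogeny.write_newick(path)


def read_distance_matrix(path: str | Path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return skbio.DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))


def write_distance_matrix(dm: skbio.DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="id"
    )


def load_inputs(
    otu_path: str | Path,
    tree_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path | None = None,
    *,
    prune_tree: bool = False,
) -> InputBundle:
    """Load and cross-validate the four pipeline inputs.

    Preconditions enforced: table OTU ids must be a subset of the tree's tip
    labels, and table sample ids must all appear in the metadata. With
    ``prune_tree`` the phylogeny is restricted to the table's OTUs.
    """
    table = read_otu_table(otu_path)
    phylogeny = read_tree(tree_path)
    metadata = read_metadata(metadata_path)

    tips = set(phylogeny.tip_labels)
    missing_otus = [o for o in table.otu_ids if o not in tips]
    if missing_otus:
        raise ValueError(
            f"OTUs in table but absent from tree: {missing_otus[:10]}"
        )
    missing_samples = [
        s for s in table.sample_ids if s not in set(metadata.sample_ids)
    ]
    if missing_samples:
        raise ValueError(
            f"samples in table but absent from metadata: {missing_samples[:10]}"
        )
    metadata = metadata.align_to(table.sample_ids)

    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
        unknown = [o for o in table.otu_ids if o not in set(taxonomy.otu_ids)]
        if unknown:
            raise ValueError(
                f"OTUs in table but absent from taxonomy: {unknown[:10]}"
            )
    if prune_tree:
        phylogeny = phylogeny.prune_to(table.otu_ids)
    return InputBundle(table, phylogeny, metadata, taxonomy)
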