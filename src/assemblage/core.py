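"""Core data containers for OTU-based community analysis.

The pipeline revolves around four cross-referenced objects: an OTU count
table (samples x OTUs, non-negative integer reads), a rooted phylogeny whose
tips are OTU ids, per-sample metadata (coordinates, season, environmental
variables) and an OTU taxonomy carrying clade labels. Containers are thin
wrappers over pandas / dendropy objects that enforce the invariants the
downstream statistics rely on (unique ids, integral counts, non-negative
branch lengths, coordinate ranges).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("summer", "winter")
UNCLASSIFIED = "unclassified"

#: canonical taxonomic ranks, most inclusive first
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class OtuTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with OTU ids as columns. Values must
        be non-negative and integral (reads).
    drop_empty:
        If True (default), OTU columns that are all-zero are silently
        dropped so the no-empty-column invariant holds; if False such
        columns raise ``ValueError``.
    """

    def __init__(self, data: pd.DataFrame, *, drop_empty: bool = True):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("OtuTable expects a pandas DataFrame")
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dup}")
        try:
            arr = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric counts in OTU table: {exc}") from exc
        if not np.isfinite(arr).all():
            raise ValueError("non-finite counts in OTU table")
        if (arr < 0).any():
            raise ValueError("negative counts in OTU table")
        if not np.array_equal(arr, np.round(arr)):
            raise ValueError("non-integer counts in OTU table")
        data = pd.DataFrame(
            arr.astype(np.int64), index=data.index, columns=data.columns
        )
        empty = data.columns[data.to_numpy().sum(axis=0) == 0]
        if len(empty):
            if not drop_empty:
                raise ValueError(
                    f"all-zero OTU columns: {list(empty)[:10]}"
                )
            logger.debug("dropping %d all-zero OTU columns", len(empty))
            data = data.drop(columns=list(empty))
        if data.shape[1] == 0:
            raise ValueError("OTU table has no non-empty OTU columns")
        if data.shape[0] == 0:
            raise ValueError("OTU table has no samples")
        self.data = data

    # -- basic accessors ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_samples, n_otus) int64 array."""
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Within-sample relative abundances (rows sum to 1)."""
        totals = self.sample_totals()
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero reads: {empty}")
        return self.data.div(totals, axis=0)

    # -- subsetting --------------------------------------------------------

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(self.data.loc[list(sample_ids)])

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.data.columns]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        return OtuTable(self.data[list(otu_ids)])

    def __eq__(self, other) -> bool:  # round-trip identity support
        return isinstance(other, OtuTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        n, t = self.shape
        return f"<OtuTable {n} samples x {t} OTUs>"


class SampleMetadata:
    """Per-sample metadata: coordinates, season/area labels, environment.

    The wrapped DataFrame is indexed by sample id. ``latitude`` and
    ``longitude`` are required and range-checked; ``season`` (summer/winter)
    and ``area`` are optional labels; any further numeric column is treated
    as an environmental variable (temperature, salinity, depth, nutrients,
    TOC, d13C, ...).
    """

    REQUIRED = ("latitude", "longitude")
    LABEL_COLUMNS = ("season", "area")

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str)
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dup}")
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        lat = pd.to_numeric(data["latitude"], errors="coerce")
        lon = pd.to_numeric(data["longitude"], errors="coerce")
        if lat.isna().any() or lon.isna().any():
            bad = data.index[lat.isna() | lon.isna()].tolist()
            raise ValueError(f"missing/non-numeric coordinates for: {bad}")
        if ((lat < -90) | (lat > 90)).any():
            bad = data.index[(lat < -90) | (lat > 90)].tolist()
            raise ValueError(f"latitude out of [-90, 90] for: {bad}")
        if ((lon < -180) | (lon > 180)).any():
            bad = data.index[(lon < -180) | (lon > 180)].tolist()
            raise ValueError(f"longitude out of [-180, 180] for: {bad}")
        data["latitude"] = lat.astype(float)
        data["longitude"] = lon.astype(float)
        if "season" in data.columns:
            bad = sorted(set(data["season"].astype(str)) - set(SEASONS))
            if bad:
                raise ValueError(
                    f"season must be one of {SEASONS}; got {bad}"
                )
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def env_columns(self) -> list[str]:
        """Numeric columns other than the coordinates."""
        cols = []
        for col in self.data.columns:
            if col in self.REQUIRED or col in self.LABEL_COLUMNS:
                continue
            if pd.api.types.is_numeric_dtype(self.data[col]):
                cols.append(col)
        return cols

    def env_matrix(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Samples x variables numeric matrix of environmental data."""
        variables = list(variables) if variables is not None else self.env_columns
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise KeyError(f"environmental variables not in metadata: {missing}")
        env = self.data[variables].apply(pd.to_numeric, errors="coerce")
        if env.isna().any().any():
            bad = env.columns[env.isna().any()].tolist()
            raise ValueError(f"non-numeric/missing values in variables: {bad}")
        return env.astype(float)

    def align_to(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return SampleMetadata(self.data.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"<SampleMetadata {len(self.data)} samples>"


class Taxonomy:
    """OTU id -> ordered rank labels plus a clade label.

    Missing or empty rank entries are normalised to the explicit
    ``"unclassified"`` marker. The ``clade`` column carries the coarse
    grouping used for per-clade analyses (e.g. "MG-I", "Woesearchaeota").
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str)
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids in taxonomy: {dup}")
        if "clade" not in data.columns:
            raise ValueError("taxonomy requires a 'clade' column")
        data = data.fillna(UNCLASSIFIED)
        for col in data.columns:
            data[col] = data[col].astype(str).replace("", UNCLASSIFIED)
        self.data = data

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def clades(self) -> list[str]:
        return sorted(self.data["clade"].unique())

    def clade_of(self, otu_id: str) -> str:
        return str(self.data.loc[otu_id, "clade"])

    def otus_in_clade(self, clade: str) -> list[str]:
        if clade not in set(self.data["clade"]):
            raise KeyError(
                f"clade {clade!r} not in taxonomy (known: {self.clades})"
            )
        return list(self.data.index[self.data["clade"] == clade])

    def __eq__(self, other) -> bool:
        return isinstance(other, Taxonomy) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"<Taxonomy {len(self.data)} OTUs, {len(self.clades)} clades>"


class Phylogeny:
    """Rooted phylogeny with branch lengths; tips are OTU ids.

    A thin wrapper over ``dendropy.Tree`` enforcing unique tip labels and
    non-negative branch lengths (the root edge may be absent). All pipeline
    code passes this wrapper; the underlying tree is available as ``.tree``.
    """

    def __init__(self, tree: dendropy.Tree):
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("phylogeny has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        root = tree.seed_node
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue  # root edge may legitimately be length-less
            if edge.length is None:
                raise ValueError("phylogeny has a missing branch length")
            if edge.length < 0:
                raise ValueError("phylogeny has a negative branch length")
        self.tree = tree

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        """Read a newick tree from a path or a newick string."""
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse errors
            raise ValueError(f"malformed newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    # -- accessors ---------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def prune_to(self, otu_ids: Iterable[str]) -> "Phylogeny":
        """Tree restricted to the given tips (e.g. the table's OTUs)."""
        keep = set(otu_ids)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)[:10]}")
        clone = dendropy.Tree(self.tree)
        clone.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(clone)

    def cophenetic_matrix(self) -> tuple[list[str], np.ndarray]:
        """Tip labels and the matrix of tip-to-tip path lengths."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = sorted(
            (leaf.taxon for leaf in self.tree.leaf_node_iter()),
            key=lambda t: t.label,
        )
        labels = [t.label for t in taxa]
        n = len(taxa)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[i], taxa[j])
                mat[i, j] = mat[j, i] = d
        return labels, mat

    def __eq__(self, other) -> bool:
        return isinstance(other, Phylogeny) and self.to_newick() == other.to_newick()

    def __repr__(self) -> str:
        return f"<Phylogeny {len(self)} tips>"
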