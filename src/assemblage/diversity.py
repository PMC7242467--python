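"""Rarefaction, sampling coverage and alpha diversity.

Alpha diversity is computed on the rarefied table: Shannon entropy (log
base configurable, default 2), bias-corrected Chao1 richness, Faith's
phylogenetic diversity (root-inclusive) and Good's coverage
``1 - F1/N`` where ``F1`` is the number of singleton OTUs in a sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon

from .core import OtuTable, Phylogeny

logger = logging.getLogger(__name__)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    The same seed always yields an identical table.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals[totals >= depth].index.tolist()
    dropped = totals[totals < depth].index.tolist()
    if dropped:
        logger.warning(
            "dropping %d samples below rarefaction depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not keep:
        raise ValueError(f"all samples are below the rarefaction depth {depth}")
    counts = table.data.loc[keep].to_numpy()
    n_otus = counts.shape[1]
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        reads = np.repeat(np.arange(n_otus), row)
        sub = rng.permutation(reads)[:depth]
        out[i] = np.bincount(sub, minlength=n_otus)
    frame = pd.DataFrame(out, index=keep, columns=table.otu_ids)
    return OtuTable(frame)


def goods_coverage(table: OtuTable) -> pd.Series:
    """Good's coverage ``1 - F1/N`` per sample, in [0, 1]."""
    counts = table.counts
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"empty samples: {empty}")
    singletons = (counts == 1).sum(axis=1)
    cov = 1.0 - singletons / totals
    return pd.Series(cov, index=table.sample_ids, name="goods_coverage")


def faith_pd(table: OtuTable, phylogeny: Phylogeny) -> pd.Series:
    """Faith's phylogenetic diversity per sample.

    Total branch length of the minimal subtree connecting a sample's
    observed OTUs to the tree root (root-inclusive convention).
    """
    tips = set(phylogeny.tip_labels)
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        raise ValueError(f"table OTUs missing from tree: {missing[:10]}")
    tree = phylogeny.tree
    postorder = list(tree.postorder_node_iter())
    values = []
    for sid in table.sample_ids:
        row = table.data.loc[sid]
        present = set(row.index[row > 0])
        if not present:
            raise ValueError(f"empty sample: {sid}")
        total = 0.0
        marked: dict[int, bool] = {}
        for node in postorder:
            if node.is_leaf():
                mark = node.taxon.label in present
            else:
                mark = any(marked[id(c)] for c in node.child_nodes())
            marked[id(node)] = mark
            if mark and node.parent_node is not None and node.edge.length:
                total += node.edge.length
        values.append(total)
    return pd.Series(values, index=table.sample_ids, name="faith_pd")


def alpha_diversity(
    table: OtuTable,
    phylogeny: Phylogeny | None = None,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample alpha diversity table.

    Columns: ``observed_otus``, ``shannon`` (in the requested log base),
    ``chao1`` (bias-corrected), ``goods_coverage`` and, when a phylogeny is
    supplied, ``faith_pd``. Warns when the table does not look rarefied
    (unequal sample totals), since the indices are depth-sensitive.
    """
    totals = table.sample_totals()
    if totals.nunique() > 1:
        logger.warning(
            "sample totals are unequal (min %d, max %d); "
            "alpha diversity is depth-sensitive — consider rarefying",
            totals.min(), totals.max(),
        )
    counts = table.counts
    observed = (counts > 0).sum(axis=1)
    shannon = np.array(
        [_skbio_shannon(row, base=log_base) for row in counts]
    )
    chao = np.array([_skbio_chao1(row, bias_corrected=True) for row in counts])
    out = pd.DataFrame(
        {
            "observed_otus": observed,
            "shannon": shannon,
            "chao1": chao,
            "goods_coverage": goods_coverage(table).to_numpy(),
        },
        index=table.sample_ids,
    )
    if phylogeny is not None:
        out["faith_pd"] = faith_pd(table, phylogeny)
    return out
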