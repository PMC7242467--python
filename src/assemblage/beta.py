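"""Bray-Curtis turnover, geography, distance-decay and PERMANOVA.

Distance-decay is the increase of community dissimilarity with geographic
distance; it is tested with a Spearman rank correlation between the lower
triangles of the Bray-Curtis and great-circle distance matrices, with a
Mantel-type label-permutation p-value (one-tailed for positive decay by
default). Per-clade decay re-extracts the clade's OTUs and recomputes the
dissimilarities within the clade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from . import _stats
from .core import OtuTable, SampleMetadata, Taxonomy

logger = logging.getLogger(__name__)

#: mean Earth radius (km) used for great-circle distances
EARTH_RADIUS_KM = 6371.0088


@dataclass
class DecayResult:
    """Spearman distance-decay statistic with permutation p-value."""

    rho: float
    p_value: float
    n_pairs: int
    n_permutations: int


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


def bray_curtis(table: OtuTable, *, normalize: bool = False) -> skbio.DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    ``normalize`` converts counts to within-sample relative abundances
    first; on a rarefied table (equal totals) the two choices coincide.
    """
    totals = table.sample_totals()
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"empty samples: {empty}")
    x = table.counts.astype(float)
    if normalize:
        x = x / x.sum(axis=1, keepdims=True)
    d = squareform(pdist(x, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return skbio.DistanceMatrix(d, ids=table.sample_ids)


def geographic_distance(metadata: SampleMetadata) -> skbio.DistanceMatrix:
    """Great-circle (haversine) distances in km between sample coordinates."""
    lat = np.radians(metadata.data["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata.data["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return skbio.DistanceMatrix(d, ids=metadata.sample_ids)


def distance_decay(
    comm: skbio.DistanceMatrix,
    geo: skbio.DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    alternative: str = "greater",
) -> DecayResult:
    """Spearman correlation between community and geographic distances.

    One-tailed by default (the decay hypothesis is directional: positive
    rho); pass ``alternative="two-sided"`` for a non-directional test.
    """
    a, b = _stats.align_ids(comm, geo)
    rho, p = _stats.mantel_correlation(
        a,
        b,
        method="spearman",
        n_permutations=n_permutations,
        seed=seed,
        alternative=alternative,
    )
    n = a.shape[0]
    return DecayResult(rho, p, n * (n - 1) // 2, n_permutations)


def subset_by_clade(
    table: OtuTable, taxonomy: Taxonomy, clade: str
) -> OtuTable:
    """Restrict the table to one clade's OTUs.

    Samples left with zero clade reads are dropped with a warning.
    """
    clade_otus = [o for o in taxonomy.otus_in_clade(clade) if o in set(table.otu_ids)]
    if not clade_otus:
        raise ValueError(f"clade {clade!r} has no OTUs in the table")
    sub = table.data[clade_otus]
    empty = sub.index[sub.sum(axis=1) == 0].tolist()
    if empty:
        logger.warning(
            "dropping %d samples with zero %s reads: %s", len(empty), clade, empty
        )
        sub = sub.drop(index=empty)
    if sub.shape[0] == 0:
        raise ValueError(f"no samples contain clade {clade!r}")
    return OtuTable(sub)


def clade_distance_decay(
    table: OtuTable,
    taxonomy: Taxonomy,
    clade: str,
    metadata: SampleMetadata,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    renormalize: bool = True,
    alternative: str = "greater",
) -> DecayResult:
    """Distance-decay of a single clade.

    Bray-Curtis is recomputed within the clade subset; ``renormalize``
    (default) uses within-clade relative abundances rather than raw reads.
    """
    sub = subset_by_clade(table, taxonomy, clade)
    comm = bray_curtis(sub, normalize=renormalize)
    geo = geographic_distance(metadata.align_to(sub.sample_ids))
    return distance_decay(
        comm, geo, n_permutations, seed, alternative=alternative
    )


def abundance_occupancy(
    table: OtuTable,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, float, float]:
    """Abundance-occupancy relationship across OTUs.

    Returns per-OTU records (mean within-sample relative abundance and the
    number of sites occupied) and the Spearman correlation between the two
    with a permutation p-value (one-tailed positive by default, mirroring
    the expected positive relationship).
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 OTUs")
    ra = table.relative_abundance().to_numpy()
    mean_ra = ra.mean(axis=0)
    occupancy = (table.counts > 0).sum(axis=0)
    records = pd.DataFrame(
        {"mean_relative_abundance": mean_ra, "occupancy": occupancy},
        index=table.otu_ids,
    )
    from scipy.stats import rankdata

    rx = rankdata(mean_ra)
    ry = rankdata(occupancy)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for t in range(n_permutations):
        perms[t] = np.corrcoef(rx, rng.permutation(ry))[0, 1]
    p = _stats.permutation_pvalue(rho, perms, alternative)
    return records, rho, p


def permanova(
    dist: skbio.DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F from the sums-of-squares partition of the (squared) distance
    matrix; the p-value permutes group labels over samples.
    """
    ids = list(dist.ids)
    if isinstance(groups, pd.Series):
        labels = groups.reindex(ids)
        if labels.isna().any():
            raise ValueError("group labels missing for some samples")
        labels = labels.astype(str).to_numpy()
    elif isinstance(groups, dict):
        labels = np.array([str(groups[i]) for i in ids])
    else:
        labels = np.asarray([str(g) for g in groups])
        if len(labels) != len(ids):
            raise ValueError("group labels do not match the sample count")
    uniq, inv = np.unique(labels, return_inverse=True)
    a = len(uniq)
    n = len(ids)
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        small = uniq[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    ss_total = _stats.condensed(d2).sum() / n
    if ss_total <= 0:
        raise ValueError("all distances are zero")

    def ss_within(assignment: np.ndarray) -> float:
        total = 0.0
        for g in range(a):
            mask = assignment == g
            ng = int(mask.sum())
            total += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
        return total

    def pseudo_f(assignment: np.ndarray) -> float:
        sw = ss_within(assignment)
        return ((ss_total - sw) / (a - 1)) / (sw / (n - a))

    sw_obs = ss_within(inv)
    f_obs = ((ss_total - sw_obs) / (a - 1)) / (sw_obs / (n - a))
    r2 = (ss_total - sw_obs) / ss_total
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for t in range(n_permutations):
        perms[t] = pseudo_f(rng.permutation(inv))
    p = _stats.permutation_pvalue(f_obs, perms, "greater")
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations)
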