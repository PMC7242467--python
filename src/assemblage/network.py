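"""Co-occurrence networks from filtered OTU tables.

Edges are Spearman correlations between OTU abundance profiles that pass
both a magnitude threshold (|rho| > 0.7) and a Benjamini-Hochberg adjusted
p-value threshold (p < 0.01), adjustment being applied over every computed
pair before thresholding. Network-level topology covers the eight features
reported for microbial co-occurrence studies (mean degree, clustering
coefficient, average path length, modularity, density, diameter,
betweenness and degree centralization); per-sample subgraphs induced on the
OTUs present in a sample support a topology distance-decay test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

from . import _stats
from .core import OtuTable, Taxonomy
from .spatial import MantelResult, mantel

logger = logging.getLogger(__name__)

#: maximum sample count for exact Spearman permutation p-values
EXACT_P_MAX_N = 9

FEATURE_COLUMNS = [
    "node_count",
    "edge_count",
    "mean_degree",
    "clustering_coefficient",
    "average_path_length",
    "modularity",
    "density",
    "diameter",
    "betweenness_centralization",
    "degree_centralization",
]


@dataclass
class TopologyFeatures:
    node_count: int
    edge_count: int
    mean_degree: float
    clustering_coefficient: float
    average_path_length: float
    modularity: float
    density: float
    diameter: int
    betweenness_centralization: float
    degree_centralization: float

    def as_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in FEATURE_COLUMNS})


def filter_otus(
    table: OtuTable,
    min_mean_ra: float = 0.0001,
    min_occurrence: float = 0.2,
) -> OtuTable:
    """Keep OTUs strictly above both abundance and occurrence thresholds.

    Retains OTUs whose mean within-sample relative abundance is strictly
    greater than ``min_mean_ra`` (default 0.01%) and whose occupancy
    fraction is strictly greater than ``min_occurrence`` (default 20% of
    samples). Both cuts are strict: an OTU sitting exactly on a threshold
    is removed.
    """
    ra = table.relative_abundance().to_numpy()
    mean_ra = ra.mean(axis=0)
    occ_frac = (table.counts > 0).mean(axis=0)
    keep = (mean_ra > min_mean_ra) & (occ_frac > min_occurrence)
    if not keep.any():
        n_ra = int((mean_ra > min_mean_ra).sum())
        n_occ = int((occ_frac > min_occurrence).sum())
        raise ValueError(
            f"no OTU passes both filters ({n_ra} pass abundance, "
            f"{n_occ} pass occurrence)"
        )
    return OtuTable(table.data.loc[:, keep])


def _spearman_pvalues(
    x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p over OTU columns.

    The p-value uses the t approximation with mid-ranked ties; for small
    sample counts (n <= 9) and tie-free column pairs the exact permutation
    distribution of the statistic is used instead (cached per n).
    Constant columns yield NaN and are reported by the caller.
    """
    n, m = x.shape
    ranks = np.array([rankdata(col) for col in x.T])  # (otus, samples)
    constant = np.array([np.ptp(col) == 0 for col in x.T])
    has_ties = np.array([len(np.unique(col)) < n for col in x.T])
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((rc * rc).sum(axis=1))
    safe = norms.copy()
    safe[constant] = 1.0
    rc_n = rc / safe[:, None]
    rho = rc_n @ rc_n.T
    np.clip(rho, -1.0, 1.0, out=rho)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    # two-sided p via the t approximation
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    pval = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    pval = np.where(np.abs(rho) >= 1.0 - 1e-12, 0.0, pval)
    if n <= EXACT_P_MAX_N:
        for i in range(m):
            if constant[i] or has_ties[i]:
                continue
            for j in range(i + 1, m):
                if constant[j] or has_ties[j]:
                    continue
                p_exact = _stats.exact_spearman_pvalue(ranks[i], ranks[j])
                pval[i, j] = pval[j, i] = p_exact
    return rho, pval, constant


def build_network(
    table: OtuTable,
    r_threshold: float = 0.7,
    p_threshold: float = 0.01,
    taxonomy: Taxonomy | None = None,
) -> nx.Graph:
    """Thresholded Spearman co-occurrence network over the table's OTUs.

    All pairwise correlations are computed, p-values are BH-adjusted over
    every tested pair, and an edge is kept iff ``|rho| > r_threshold`` and
    adjusted ``p < p_threshold``. Isolated OTUs are dropped. Edge
    attributes: ``rho``, ``p_adjusted``, ``sign``; node attribute
    ``clade`` when a taxonomy is given.
    """
    n, m = table.shape
    if n < 5:
        raise ValueError("need at least 5 samples to build a network")
    if m < 2:
        raise ValueError("need at least 2 OTUs")
    x = table.counts.astype(float)
    rho, pval, constant = _spearman_pvalues(x)
    if constant.any():
        skipped = [o for o, c in zip(table.otu_ids, constant) if c]
        logger.warning(
            "skipping %d constant OTU profiles: %s", len(skipped), skipped[:10]
        )
    iu, ju = np.triu_indices(m, k=1)
    ok = ~(constant[iu] | constant[ju])
    iu, ju = iu[ok], ju[ok]
    raw_p = pval[iu, ju]
    _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    keep = (np.abs(rho[iu, ju]) > r_threshold) & (p_adj < p_threshold)
    graph = nx.Graph()
    otus = np.array(table.otu_ids)
    for i, j, r, p in zip(iu[keep], ju[keep], rho[iu, ju][keep], p_adj[keep]):
        graph.add_edge(
            str(otus[i]),
            str(otus[j]),
            rho=float(r),
            p_adjusted=float(p),
            sign=1 if r > 0 else -1,
        )
    if taxonomy is not None:
        known = set(taxonomy.otu_ids)
        for node in graph.nodes:
            graph.nodes[node]["clade"] = (
                taxonomy.clade_of(node) if node in known else "unclassified"
            )
    return graph


# ---------------------------------------------------------------------------
# topology


def _modularity_partition(graph: nx.Graph) -> tuple[list[set], float]:
    if graph.number_of_edges() == 0:
        return [{n} for n in graph.nodes], 0.0
    communities = list(
        nx.algorithms.community.greedy_modularity_communities(graph)
    )
    q = nx.algorithms.community.modularity(graph, communities)
    return [set(c) for c in communities], float(q)


def topology(graph: nx.Graph) -> TopologyFeatures:
    """Network-level topology of a co-occurrence graph.

    Average path length and diameter are computed on the largest connected
    component; modularity uses deterministic greedy (CNM) agglomeration.
    Degenerate sizes (fewer than 3 nodes) report zero centralization.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    e = graph.number_of_edges()
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    mean_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    clustering = nx.transitivity(graph)
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        logger.debug("graph has %d connected components", len(components))
    giant = graph.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diameter = nx.diameter(giant)
    else:
        apl, diameter = 0.0, 0
    _, q = _modularity_partition(graph)
    if n > 2:
        degree_centralization = float(
            (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
        )
        btw = np.array(
            list(nx.betweenness_centrality(graph, normalized=True).values())
        )
        betweenness_centralization = float((btw.max() - btw).sum() / (n - 1))
    else:
        degree_centralization = 0.0
        betweenness_centralization = 0.0
    return TopologyFeatures(
        node_count=n,
        edge_count=e,
        mean_degree=float(mean_degree),
        clustering_coefficient=float(clustering),
        average_path_length=float(apl),
        modularity=q,
        density=float(density),
        diameter=int(diameter),
        betweenness_centralization=betweenness_centralization,
        degree_centralization=degree_centralization,
    )


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree, local clustering, betweenness and closeness.

    Closeness is component-restricted: reachable count divided by the sum
    of distances to reachable nodes (a node in an isolated dyad scores 1).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = dict(graph.degree())
    local_clustering = nx.clustering(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    nodes = sorted(graph.nodes)
    return pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "transitivity": [local_clustering[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
        },
        index=nodes,
    )


def assign_modules(graph: nx.Graph) -> dict[str, int]:
    """Greedy-modularity module index per node (stored as node attr)."""
    communities, _ = _modularity_partition(graph)
    membership: dict[str, int] = {}
    for idx, community in enumerate(
        sorted(communities, key=len, reverse=True)
    ):
        for node in community:
            membership[node] = idx
    nx.set_node_attributes(graph, membership, "module")
    return membership


# ---------------------------------------------------------------------------
# per-sample subgraphs and topology decay


def sample_subgraph(
    graph: nx.Graph, table: OtuTable, sample_id: str
) -> nx.Graph:
    """Subgraph induced on the network OTUs present in one sample."""
    if sample_id not in set(table.sample_ids):
        raise KeyError(f"unknown sample id {sample_id!r}")
    row = table.data.loc[sample_id]
    present = {o for o in row.index[row > 0] if o in graph}
    return graph.subgraph(present).copy()


def sample_topology_table(graph: nx.Graph, table: OtuTable) -> pd.DataFrame:
    """Ten topology features of every sample's induced subgraph.

    Samples whose subgraph is empty are excluded with a warning. Subgraphs
    with nodes but no edges report zero path length, diameter and
    modularity.
    """
    rows, index, empty = [], [], []
    for sid in table.sample_ids:
        sub = sample_subgraph(graph, table, sid)
        if sub.number_of_nodes() == 0:
            empty.append(sid)
            continue
        rows.append(topology(sub).as_series())
        index.append(sid)
    if empty:
        logger.warning(
            "samples with empty network subgraphs excluded: %s", empty
        )
    if not rows:
        raise ValueError("no sample has a non-empty subgraph")
    return pd.DataFrame(rows, index=index)


def topology_decay(
    features: pd.DataFrame,
    geo: skbio.DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of between-sample topology distance against geography.

    The topology distance is Euclidean over the z-scored feature columns;
    zero-variance features are dropped with a warning (all features
    invariant means no decay is testable and raises).
    """
    if features.shape[0] < 4:
        raise ValueError("need at least 4 samples with computable features")
    x = features.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError(
            "all topology features are constant across samples; "
            "no decay testable"
        )
    if not keep.all():
        dropped = list(features.columns[~keep])
        logger.warning("dropping zero-variance features: %s", dropped)
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    feat_dm = skbio.DistanceMatrix(
        squareform(pdist(z)), ids=list(features.index)
    )
    geo = geo.filter(list(features.index))
    return mantel(
        feat_dm,
        geo,
        method="pearson",
        n_permutations=n_permutations,
        seed=seed,
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# writers


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path), infer_numeric_types=True)


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "rho": d.get("rho"),
            "p_adjusted": d.get("p_adjusted"),
            "sign": d.get("sign"),
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "rho", "p_adjusted", "sign"]
    ).to_csv(path, sep="\t", index=False)
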