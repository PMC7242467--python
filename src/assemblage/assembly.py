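"""Phylogenetic and Raup-Crick null models for community assembly.

The five-process framework partitions pairwise community turnover into
ecological processes. For each unordered pair of samples:

* betaMNTD, the abundance-weighted mean distance from each taxon to its
  nearest relative in the other sample, measures phylogenetic turnover;
* betaNTI standardises the observed betaMNTD against a null distribution
  obtained by shuffling taxa across the phylogeny's tips (richness and
  abundances held fixed). ``betaNTI > 2`` marks heterogeneous selection and
  ``betaNTI < -2`` homogeneous selection;
* for the remaining (stochastic) pairs, the Bray-Curtis Raup-Crick metric
  ``RC_bray`` compares the observed dissimilarity with probabilistically
  reassembled null communities. ``RC_bray > 0.95`` marks dispersal
  limitation, ``RC_bray < -0.95`` homogenizing dispersal, the remainder
  drift.

The framework's precondition — phylogenetic signal in species niches over
short phylogenetic distances — is checked with a Mantel correlogram between
between-OTU niche-optimum distances and phylogenetic distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from statsmodels.stats.multitest import multipletests

from . import _stats
from .core import OtuTable, Phylogeny, SampleMetadata

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

#: selection threshold on the standardised phylogenetic turnover
BNTI_THRESHOLD = 2.0
#: dispersal/drift threshold on the Raup-Crick metric
RC_THRESHOLD = 0.95

_SD_EPS = 1e-12


@dataclass
class ProcessFractions:
    """Aggregate five-way process fractions over classified pairs."""

    fractions: dict[str, float]
    stochasticity_ratio: float
    n_pairs: int
    n_undefined: int = 0

    def as_dict(self) -> dict:
        out = dict(self.fractions)
        out["stochasticity_ratio"] = self.stochasticity_ratio
        out["n_pairs"] = self.n_pairs
        out["n_undefined"] = self.n_undefined
        return out


@dataclass
class BetaNullResult:
    """Per-pair null-model results in long format.

    ``pairs`` columns: sample_a, sample_b, bmntd_obs, null_mean, null_sd,
    bnti, and (after the Raup-Crick and classification steps) rc_bray and
    process.
    """

    pairs: pd.DataFrame
    n_null: int
    weighted: bool = True
    fractions: ProcessFractions | None = None


# ---------------------------------------------------------------------------
# phylogenetic distances and niche optima


def cophenetic_distances(phylogeny: Phylogeny) -> skbio.DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances."""
    labels, mat = phylogeny.cophenetic_matrix()
    return skbio.DistanceMatrix(mat, ids=labels)


def niche_optima(
    table: OtuTable,
    metadata: SampleMetadata,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Abundance-weighted environmental optimum of each OTU.

    ``optimum(i, v) = sum_s x_si * v_s / sum_s x_si`` — a convex combination
    of the observed values, so every optimum lies inside the variable's
    observed range.
    """
    env = metadata.align_to(table.sample_ids).env_matrix(variables)
    x = table.counts.astype(float)
    colsum = x.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("all-zero OTU column")  # guarded by OtuTable
    w = x / colsum  # (samples x otus), columns sum to 1
    opt = w.T @ env.to_numpy()
    return pd.DataFrame(opt, index=table.otu_ids, columns=env.columns)


def niche_distance(optima: pd.DataFrame) -> skbio.DistanceMatrix:
    """Euclidean between-OTU distance over z-scored optimum columns."""
    z = optima.to_numpy(dtype=float).copy()
    sd = z.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all niche-optimum columns have zero variance")
    if not keep.all():
        dropped = list(optima.columns[~keep])
        logger.warning("dropping zero-variance optimum columns: %s", dropped)
    z = (z[:, keep] - z[:, keep].mean(axis=0)) / sd[keep]
    from scipy.spatial.distance import pdist, squareform

    return skbio.DistanceMatrix(
        squareform(pdist(z)), ids=list(optima.index)
    )


def phylogenetic_signal_correlogram(
    optima: pd.DataFrame,
    phylo: skbio.DistanceMatrix,
    n_classes: int = 10,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    min_pairs: int = 10,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Phylogenetic distances are cut into ``n_classes`` equal-width classes;
    within each class the Mantel statistic is the (sign-flipped) correlation
    between the class-membership indicator and the niche distance, so a
    positive r means OTU pairs in that class are ecologically more similar
    than average — phylogenetic signal when it occurs at short distances.
    P-values permute OTU labels of the niche matrix and are corrected across
    tested classes with Holm's sequential procedure. Classes with fewer
    than ``min_pairs`` pairs are reported but not tested.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 distance classes")
    ids = list(optima.index)
    if set(ids) != set(phylo.ids):
        raise ValueError("optima OTUs do not match phylogenetic-distance OTUs")
    nd = niche_distance(optima)
    d_phy = np.asarray(phylo.filter(ids).data, dtype=float)
    d_nic = np.asarray(nd.data, dtype=float)
    n = len(ids)
    il, jl = np.tril_indices(n, k=-1)
    y = d_nic[il, jl]
    x = d_phy[il, jl]
    edges = np.linspace(0.0, x.max(), n_classes + 1)
    # class k: (edges[k], edges[k+1]], first class closed on the left
    cls = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, n_classes - 1)

    indicators = np.zeros((n_classes, len(y)))
    n_pairs = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        mask = cls == k
        n_pairs[k] = int(mask.sum())
        indicators[k] = mask.astype(float)
    # centered, normalised indicators; degenerate (empty/full) classes -> nan
    ic = indicators - indicators.mean(axis=1, keepdims=True)
    norms = np.sqrt((ic * ic).sum(axis=1))
    valid = norms > 0
    ic[valid] = ic[valid] / norms[valid, None]

    def class_r(yvec: np.ndarray) -> np.ndarray:
        yc = yvec - yvec.mean()
        ynorm = np.sqrt(yc @ yc)
        if ynorm == 0:
            raise ValueError("zero variance in niche distances")
        r = np.full(n_classes, np.nan)
        r[valid] = -(ic[valid] @ yc) / ynorm
        return r

    r_obs = class_r(y)
    tested = valid & (n_pairs >= min_pairs)
    p_raw = np.full(n_classes, np.nan)
    if n_permutations > 0:
        if seed is None:
            raise ValueError("seed is required for the permutation test")
        rng = np.random.default_rng(seed)
        perm_r = np.empty((n_permutations, n_classes))
        for t in range(n_permutations):
            idx = rng.permutation(n)
            perm_r[t] = class_r(d_nic[idx[:, None], idx[None, :]][il, jl])
        for k in np.where(tested)[0]:
            p_raw[k] = _stats.permutation_pvalue(
                r_obs[k], perm_r[:, k], alternative
            )
    p_adj = np.full(n_classes, np.nan)
    signif = np.zeros(n_classes, dtype=bool)
    t_idx = np.where(tested & ~np.isnan(p_raw))[0]
    if len(t_idx):
        rej, adj, _, _ = multipletests(p_raw[t_idx], method="holm")
        p_adj[t_idx] = adj
        signif[t_idx] = rej
    return pd.DataFrame(
        {
            "lower": edges[:-1],
            "upper": edges[1:],
            "n_pairs": n_pairs,
            "mantel_r": r_obs,
            "p_value": p_raw,
            "p_adjusted": p_adj,
            "significant": signif,
            "tested": tested,
        }
    )


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def _aligned_cophenetic(table: OtuTable, phylo) -> np.ndarray:
    if isinstance(phylo, Phylogeny):
        phylo = cophenetic_distances(phylo)
    missing = [o for o in table.otu_ids if o not in set(phylo.ids)]
    if missing:
        raise ValueError(f"table OTUs missing from phylogeny: {missing[:10]}")
    return np.asarray(phylo.filter(table.otu_ids).data, dtype=float)


def _abundance_weights(table: OtuTable, weighted: bool) -> np.ndarray:
    x = table.counts.astype(float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("empty sample")
    if weighted:
        return x / x.sum(axis=1, keepdims=True)
    pres = (x > 0).astype(float)
    return pres / pres.sum(axis=1, keepdims=True)


def _bmntd_from_parts(
    d: np.ndarray, presence: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """betaMNTD for all sample pairs given an (otus x otus) distance matrix.

    ``M[m, i] = min_{j present in m} d[i, j]`` (zero for taxa shared with
    m); the pair value is the two-way abundance-weighted average of nearest
    -taxon distances.
    """
    n = presence.shape[0]
    m = np.empty((n, d.shape[0]))
    for s in range(n):
        m[s] = d[:, presence[s]].min(axis=1)
    b = weights @ m.T  # b[k, m] = sum_i f_ik * min-dist to community m
    out = 0.5 * (b + b.T)
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(
    table: OtuTable, phylo, *, weighted: bool = True
) -> skbio.DistanceMatrix:
    """Between-sample phylogenetic turnover (betaMNTD).

    ``phylo`` may be a :class:`Phylogeny` or a cophenetic
    ``skbio.DistanceMatrix``. Shared taxa contribute distance zero (a taxon
    is its own nearest neighbour), so identical communities score 0.
    """
    d = _aligned_cophenetic(table, phylo)
    presence = table.counts > 0
    weights = _abundance_weights(table, weighted)
    return skbio.DistanceMatrix(
        _bmntd_from_parts(d, presence, weights), ids=table.sample_ids
    )


def beta_nti(
    table: OtuTable,
    phylo,
    n_null: int = 999,
    seed: int | None = None,
    *,
    weighted: bool = True,
) -> BetaNullResult:
    """Standardised betaMNTD against a taxa-shuffle null model.

    Each null draw relabels the taxa across the phylogeny's tips (a joint
    row/column permutation of the cophenetic matrix) and recomputes
    betaMNTD; ``bnti = (obs - null_mean) / null_sd``. Pairs whose null
    distribution is degenerate (sd ~ 0, e.g. on a star phylogeny) get
    ``bnti = NaN`` and are flagged in the log.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if seed is None:
        raise ValueError("seed is required for the null model")
    d = _aligned_cophenetic(table, phylo)
    presence = table.counts > 0
    weights = _abundance_weights(table, weighted)
    obs = _bmntd_from_parts(d, presence, weights)
    n = presence.shape[0]
    t = d.shape[0]
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, n, n))
    for it in range(n_null):
        perm = rng.permutation(t)
        nulls[it] = _bmntd_from_parts(
            d[perm[:, None], perm[None, :]], presence, weights
        )
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(
            null_sd > _SD_EPS, (obs - null_mean) / null_sd, np.nan
        )
    il, jl = np.tril_indices(n, k=-1)
    undefined = int(np.isnan(bnti[il, jl]).sum())
    if undefined:
        logger.warning(
            "betaNTI undefined (degenerate null) for %d pairs", undefined
        )
    ids = np.array(table.sample_ids)
    pairs = pd.DataFrame(
        {
            "sample_a": ids[jl],
            "sample_b": ids[il],
            "bmntd_obs": obs[il, jl],
            "null_mean": null_mean[il, jl],
            "null_sd": null_sd[il, jl],
            "bnti": bnti[il, jl],
        }
    )
    return BetaNullResult(pairs=pairs, n_null=n_null, weighted=weighted)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)


def raup_crick_bray(
    table: OtuTable, n_null: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Bray-Curtis Raup-Crick metric for every unordered sample pair.

    The metacommunity is the full input table: null communities draw the
    observed richness of species without replacement with probability
    proportional to occupancy frequency, seed each drawn species with one
    read, and distribute the remaining reads multinomially in proportion to
    metacommunity relative abundance. ``rc_bray`` rescales the rank of the
    observed Bray-Curtis within the null distribution to [-1, 1] with ties
    counted at half weight.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if seed is None:
        raise ValueError("seed is required for the null model")
    x = table.counts
    n, t = x.shape
    occupancy = (x > 0).sum(axis=0).astype(float)
    gamma = x.sum(axis=0).astype(float)
    gamma = gamma / gamma.sum()
    richness = (x > 0).sum(axis=1)
    totals = x.sum(axis=1)
    if (richness > t).any():  # pragma: no cover - impossible by construction
        raise RuntimeError("sample richness exceeds the metacommunity pool")
    rng = np.random.default_rng(seed)
    log_occ = np.log(occupancy)  # every retained OTU occurs somewhere
    nulls = np.zeros((n, n_null, t), dtype=np.int64)
    for k in range(n):
        r, total = int(richness[k]), int(totals[k])
        # weighted sampling without replacement via Gumbel top-k
        keys = log_occ + rng.gumbel(size=(n_null, t))
        sel = np.argpartition(-keys, r - 1, axis=1)[:, :r]
        for it in range(n_null):
            s = sel[it]
            p = gamma[s]
            p = p / p.sum()
            nulls[k, it, s] = 1 + rng.multinomial(total - r, p)
    obs_x = x.astype(float)
    il, jl = np.tril_indices(n, k=-1)
    rows = []
    ids = np.array(table.sample_ids)
    for a, b in zip(jl, il):  # a < b
        num = np.abs(obs_x[a] - obs_x[b]).sum()
        den = (obs_x[a] + obs_x[b]).sum()
        bc_obs = num / den
        diff = np.abs(nulls[a] - nulls[b]).sum(axis=1)
        denom = (nulls[a] + nulls[b]).sum(axis=1)
        bc_null = diff / denom
        less = int(np.sum(bc_null < bc_obs - _stats.TIE_EPS))
        ties = int(np.sum(np.abs(bc_null - bc_obs) <= _stats.TIE_EPS))
        rc = 2.0 * ((less + 0.5 * ties) / n_null - 0.5)
        rows.append((ids[a], ids[b], bc_obs, rc))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bray_curtis", "rc_bray"]
    )


# ---------------------------------------------------------------------------
# classification


def classify_pair(bnti: float, rc_bray: float) -> str:
    """Five-way process label for one sample pair."""
    if np.isnan(bnti):
        return "undefined"
    if bnti > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_bray > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_bray < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def classify_processes(
    pairs: pd.DataFrame,
) -> tuple[pd.DataFrame, ProcessFractions]:
    """Label every pair and aggregate the five-way process fractions.

    ``pairs`` needs ``bnti`` and ``rc_bray`` columns. Pairs with undefined
    betaNTI are excluded from the fractions and counted separately. The
    stochasticity ratio is the summed fraction of the three stochastic
    processes (dispersal limitation, homogenizing dispersal, drift).
    """
    for col in ("bnti", "rc_bray"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table lacks column {col!r}")
    pairs = pairs.copy()
    pairs["process"] = [
        classify_pair(b, r) for b, r in zip(pairs["bnti"], pairs["rc_bray"])
    ]
    defined = pairs[pairs["process"] != "undefined"]
    n_def = len(defined)
    n_undef = len(pairs) - n_def
    if n_def == 0:
        raise ValueError("no pairs with defined betaNTI")
    counts = defined["process"].value_counts()
    fractions = {p: float(counts.get(p, 0)) / n_def for p in PROCESSES}
    stoch = (
        fractions["dispersal_limitation"]
        + fractions["homogenizing_dispersal"]
        + fractions["drift"]
    )
    return pairs, ProcessFractions(
        fractions=fractions,
        stochasticity_ratio=stoch,
        n_pairs=n_def,
        n_undefined=n_undef,
    )


def assembly_analysis(
    table: OtuTable,
    phylo,
    n_null: int = 999,
    seed: int | None = None,
    *,
    weighted: bool = True,
) -> BetaNullResult:
    """Full null-model pass: betaNTI, RC_bray and process classification."""
    if seed is None:
        raise ValueError("seed is required for the null models")
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    result = beta_nti(
        table, phylo, n_null=n_null, seed=int(seeds[0]), weighted=weighted
    )
    rc = raup_crick_bray(table, n_null=n_null, seed=int(seeds[1]))
    merged = result.pairs.merge(rc, on=["sample_a", "sample_b"], how="left")
    labeled, fractions = classify_processes(merged)
    result.pairs = labeled
    result.fractions = fractions
    return result
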