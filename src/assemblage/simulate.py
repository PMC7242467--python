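"""Synthetic metacommunities with known assembly regimes.

The generator builds a Yule phylogeny with Brownian-motion niche optima
(phylogenetically conserved environmental preferences), a long-tailed
regional species pool, spatial sample layouts with a temperature-like
environmental gradient, and local communities of fixed size J assembled
under one of five regimes:

* ``heterogeneous_selection`` — strong environmental gradient, narrow
  Gaussian environmental filter around each taxon's optimum;
* ``homogeneous_selection`` — the same narrow filter under a spatially
  constant environment;
* ``dispersal_limitation`` — neutral weights, with isolated patches whose
  local pools have independently drifted away from the regional pool;
* ``homogenizing_dispersal`` — mass effect: all samples share one realized
  community, each refreshed by a small immigrant fraction;
* ``drift`` — neutral weights, independent demographic realizations of the
  regional pool.

Every dataset is fully reproducible from its configuration and seed, and is
emitted in the exact containers and plain-text formats the analysis modules
consume.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .assembly import PROCESSES
from .core import OtuTable, Phylogeny, SampleMetadata, Taxonomy, UNCLASSIFIED

#: km per degree of latitude on the reference sphere
KM_PER_DEGREE = 111.19492664455873


@dataclass
class SimulationConfig:
    """Knobs of the metacommunity generator.

    Defaults mirror a coastal-sediment amplicon survey: 58 samples along a
    ~1500 km transect rarefied to 12630 reads, a long-tailed pool, a
    temperature-like 1D gradient, and Brownian (phylogenetically conserved)
    thermal optima.
    """

    regime: str = "drift"
    n_samples: int = 58
    n_taxa: int = 1000
    reads_per_sample: int = 12630  # local community size J
    selection_width: float = 2.0  # sigma_w, environment units (deg C)
    niche_breadth: float = 0.15  # fraction of taxa inside a niche window
    colonization_rate: float = 0.5  # lottery membership prob. (selection)
    immigrant_rain: float = 0.002  # uniform immigrant read fraction
    migration_rate: float = 0.05  # fresh-immigrant fraction (mass effect)
    n_patches: int = 4
    env_range: tuple[float, float] = (5.0, 25.0)
    extent_km: float = 1500.0
    layout: str = "line"  # or "grid"
    brownian_rate: float = 6.0  # sigma_BM of optimum evolution
    late_rate_factor: float = 0.15  # early-burst rate drop below clade depth
    pool_shape: float = 0.03  # geometric rank-abundance decay
    drift_pool_size: int = 500  # effective size of drifting patch pools
    drift_generations: int = 30
    sample_drift_size: int = 2000  # per-sample demographic drift (drift regime)
    sample_drift_generations: int = 1
    clade_count: int = 5
    clade_depth: float = 0.5  # depth cut defining synthetic clades
    env_noise: float = 0.2  # measurement-scale noise on the gradient
    seed: int = 0

    def validate(self) -> None:
        if self.regime not in PROCESSES:
            raise ValueError(
                f"unknown regime {self.regime!r}; expected one of {PROCESSES}"
            )
        if self.n_samples < 2 or self.n_taxa < 3 or self.reads_per_sample < 1:
            raise ValueError("sizes must be positive (>=2 samples, >=3 taxa)")
        if self.selection_width <= 0:
            raise ValueError("selection_width must be > 0")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must lie in [0, 1]")
        if self.n_patches < 1 or self.n_patches > self.n_samples:
            raise ValueError("n_patches must lie in [1, n_samples]")
        if self.layout not in ("line", "grid"):
            raise ValueError("layout must be 'line' or 'grid'")


@dataclass
class SyntheticDataset:
    """Simulated table, tree and metadata with the generating regime."""

    table: OtuTable
    phylogeny: Phylogeny
    metadata: SampleMetadata
    taxonomy: Taxonomy
    true_regime: str
    niche_optima: pd.Series
    config: SimulationConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------


def simulate_phylogeny(n_taxa: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree rescaled to unit root depth, tips OTU_1..n."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=_pyrandom.Random(int(seed)),
    )
    rng = _pyrandom.Random(int(seed) + 1)
    # observe the tree between the n-th and (n+1)-th speciation: extend every
    # tip edge by the same Exp(n * birth_rate) waiting time (keeps the last
    # cherry from having zero-length branches, stays ultrametric)
    extra = rng.expovariate(float(n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU_{i + 1}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None  # drop the stem above the root
    depth = tree.max_distance_from_root()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return Phylogeny(tree)


def evolve_niche_optima(
    phylogeny: Phylogeny,
    sigma_bm: float,
    root_value: float = 0.0,
    seed: int = 0,
    *,
    rate_shift_depth: float | None = None,
    late_rate_factor: float = 1.0,
) -> pd.Series:
    """Brownian-motion trait evolution of niche optima along the tree.

    Each branch adds a Normal(0, sigma_bm^2 * branch_length) increment, so
    tip variance grows with root-to-tip length and closely related tips
    share correlated optima — the phylogenetic signal the null-model
    framework presupposes. With ``rate_shift_depth`` the evolutionary rate
    drops to ``late_rate_factor * sigma_bm`` below that depth (an
    early-burst model), concentrating trait divergence on the deep
    branches so optima are conserved within clades.
    """
    if sigma_bm < 0:
        raise ValueError("sigma_bm must be >= 0")
    rng = np.random.default_rng(int(seed))
    values: dict[int, float] = {}
    depths: dict[int, float] = {}
    tree = phylogeny.tree
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = float(root_value)
            depths[id(node)] = 0.0
        else:
            parent = node.parent_node
            length = node.edge.length or 0.0
            depths[id(node)] = depths[id(parent)] + length
            if rate_shift_depth is None:
                var = sigma_bm**2 * length
            else:
                early = max(0.0, min(length, rate_shift_depth - depths[id(parent)]))
                var = sigma_bm**2 * (early + late_rate_factor**2 * (length - early))
            step = rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
            values[id(node)] = values[id(parent)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="niche_optimum")


def _regional_pool(n_taxa: int, shape: float, rng: np.random.Generator) -> np.ndarray:
    """Long-tailed (geometric rank-abundance) pool, randomly tied to taxa."""
    ranks = np.arange(n_taxa)
    p = (1.0 - shape) ** ranks
    p = p / p.sum()
    return rng.permutation(p)


def _coordinates(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sample positions (km) along a line or on a grid."""
    n = config.n_samples
    if config.layout == "line":
        xs = np.linspace(0.0, config.extent_km, n)
        ys = np.zeros(n)
    else:
        side = int(np.ceil(np.sqrt(n)))
        gx, gy = np.meshgrid(
            np.linspace(0.0, config.extent_km, side),
            np.linspace(0.0, config.extent_km, side),
        )
        xs = gx.ravel()[:n]
        ys = gy.ravel()[:n]
    return xs, ys


def _drifted_pool(
    pool: np.ndarray,
    generations: int,
    effective_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Neutral drift: sequential multinomial resampling of a finite pool."""
    freq = pool.copy()
    for _ in range(generations):
        counts = rng.multinomial(effective_size, freq)
        freq = counts / effective_size
    return freq


def _clade_labels(phylogeny: Phylogeny, depth_cut: float, k: int) -> pd.Series:
    """Synthetic clades: the k largest subtrees crossing a fixed depth cut."""
    tree = phylogeny.tree
    groups: list[list[str]] = []
    depths: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        pdepth = depths[id(parent)] if parent is not None else 0.0
        depth = pdepth + (node.edge.length or 0.0)
        depths[id(node)] = depth
        if pdepth < depth_cut <= depth or (
            parent is None and depth >= depth_cut
        ):
            groups.append(
                [leaf.taxon.label for leaf in node.leaf_iter()]
            )
    groups.sort(key=len, reverse=True)
    labels: dict[str, str] = {}
    for idx, tips in enumerate(groups):
        name = f"Clade_{idx + 1:02d}" if idx < k else "Clade_other"
        for tip in tips:
            labels[tip] = name
    for tip in phylogeny.tip_labels:  # tips entirely above the cut
        labels.setdefault(tip, "Clade_other")
    return pd.Series(labels, name="clade")


def _assemble_counts(
    config: SimulationConfig,
    pool: np.ndarray,
    optima: np.ndarray,
    env: np.ndarray,
    patch_of: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n, j = config.n_samples, config.reads_per_sample
    t = config.n_taxa
    counts = np.zeros((n, t), dtype=np.int64)
    regime = config.regime
    if regime in ("heterogeneous_selection", "homogeneous_selection"):
        # narrow Gaussian filter inside a hard niche window (the taxa whose
        # optima are closest to the local environment), with a colonization
        # lottery for membership turnover and a thin uniform immigrant rain
        # so the pooled table spans the whole phylogeny
        sw2 = 2.0 * config.selection_width**2
        k_window = max(3, int(round(config.niche_breadth * t)))
        rain = np.full(t, 1.0 / t)
        m = config.immigrant_rain
        for s in range(n):
            gap = np.abs(optima - env[s])
            window = np.zeros(t)
            window[np.argsort(gap)[:k_window]] = 1.0
            filt = window * np.exp(-(gap**2) / sw2)
            mask = rng.random(t) < config.colonization_rate
            w_sel = filt * mask
            if w_sel.sum() == 0:
                w_sel = filt
            w = (1.0 - m) * w_sel / w_sel.sum() + m * rain
            counts[s] = rng.multinomial(j, w / w.sum())
    elif regime == "drift":
        for s in range(n):
            local = _drifted_pool(
                pool, config.sample_drift_generations,
                config.sample_drift_size, rng,
            )
            counts[s] = rng.multinomial(j, local)
    elif regime == "homogenizing_dispersal":
        shared = rng.multinomial(j, pool)
        for s in range(n):
            fresh = rng.binomial(j, config.migration_rate)
            kept = rng.multivariate_hypergeometric(shared, j - fresh)
            counts[s] = kept + rng.multinomial(fresh, pool)
    elif regime == "dispersal_limitation":
        patch_pools = {
            p: _drifted_pool(
                pool, config.drift_generations, config.drift_pool_size, rng
            )
            for p in np.unique(patch_of)
        }
        for s in range(n):
            counts[s] = rng.multinomial(j, patch_pools[patch_of[s]])
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(f"unknown regime {regime!r}")
    return counts


def simulate_metacommunity(config: SimulationConfig) -> SyntheticDataset:
    """Simulate one dataset under the configured assembly regime."""
    config.validate()
    ss = np.random.SeedSequence(int(config.seed))
    seeds = ss.generate_state(4) % (2**31)
    tree = simulate_phylogeny(config.n_taxa, int(seeds[0]))
    env_mid = 0.5 * (config.env_range[0] + config.env_range[1])
    optima_series = evolve_niche_optima(
        tree,
        config.brownian_rate,
        root_value=env_mid,
        seed=int(seeds[1]),
        rate_shift_depth=config.clade_depth,
        late_rate_factor=config.late_rate_factor,
    )
    rng = np.random.default_rng(int(seeds[2]))

    taxa = [f"OTU_{i + 1}" for i in range(config.n_taxa)]
    optima = optima_series.reindex(taxa).to_numpy()
    pool = _regional_pool(config.n_taxa, config.pool_shape, rng)

    xs, ys = _coordinates(config)
    # contiguous patches along the transect order
    patch_of = np.minimum(
        (np.arange(config.n_samples) * config.n_patches) // config.n_samples,
        config.n_patches - 1,
    )
    lo, hi = config.env_range
    if config.regime == "heterogeneous_selection":
        env = lo + (hi - lo) * xs / max(xs.max(), 1.0)
    elif config.regime == "homogeneous_selection":
        # a consistently extreme environment: selection for one end of the
        # niche axis, where clade-conserved optima are most clustered
        env = np.full(config.n_samples, hi)
    else:
        env = np.full(config.n_samples, env_mid)
    env = env + rng.normal(0.0, config.env_noise, size=config.n_samples)

    counts = _assemble_counts(config, pool, optima, env, patch_of, rng)
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    table = OtuTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxa)
    )

    lat0, lon0 = 24.0, 122.0
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "latitude": lat0 + ys / KM_PER_DEGREE
                if config.layout == "grid"
                else lat0 + xs / KM_PER_DEGREE,
                "longitude": lon0 + (xs / KM_PER_DEGREE if config.layout == "grid" else 0.0),
                "season": [
                    ("summer", "winter")[i % 2] for i in range(config.n_samples)
                ],
                "area": [f"area_{p + 1}" for p in patch_of],
                "temperature": env,
                "salinity": rng.normal(31.0, 1.0, size=config.n_samples),
                "water_depth": 20.0
                + 60.0 * xs / max(xs.max(), 1.0)
                + rng.normal(0.0, 5.0, size=config.n_samples),
                "toc": np.abs(rng.normal(0.6, 0.15, size=config.n_samples)),
            },
            index=sample_ids,
        )
    )
    clades = _clade_labels(tree, config.clade_depth, config.clade_count)
    taxonomy = Taxonomy(
        pd.DataFrame(
            {
                "domain": "Archaea",
                "phylum": UNCLASSIFIED,
                "class": UNCLASSIFIED,
                "order": UNCLASSIFIED,
                "family": UNCLASSIFIED,
                "genus": UNCLASSIFIED,
                "clade": clades.reindex(taxa).to_numpy(),
            },
            index=taxa,
        )
    )
    return SyntheticDataset(
        table=table,
        phylogeny=tree,
        metadata=metadata,
        taxonomy=taxonomy,
        true_regime=config.regime,
        niche_optima=optima_series,
        config=config,
    )


def demo_config(regime: str, seed: int = 0) -> SimulationConfig:
    """Small demo conditions: 12 samples x 200 OTUs at 5000 reads."""
    return SimulationConfig(
        regime=regime,
        n_samples=12,
        n_taxa=200,
        reads_per_sample=5000,
        n_patches=3,
        seed=seed,
    )


def write_demo_fixtures(outdir, regimes=PROCESSES, seed: int = 0) -> dict:
    """Write one small demo dataset per regime in the pipeline's formats."""
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for regime in regimes:
        dataset = simulate_metacommunity(demo_config(regime, seed=seed))
        base = outdir / regime
        base.mkdir(exist_ok=True)
        _io.write_otu_table(dataset.table, base / "otu_table.tsv")
        _io.write_tree(dataset.phylogeny, base / "tree.nwk")
        _io.write_metadata(dataset.metadata, base / "metadata.tsv")
        _io.write_taxonomy(dataset.taxonomy, base / "taxonomy.tsv")
        paths[regime] = base
    return paths
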