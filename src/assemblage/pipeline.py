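"""End-to-end orchestration with a YAML configuration and a run report.

Stages run in the analysis order: load/simulate -> rarefy -> alpha ->
beta (+ whole-community and per-clade distance-decay) -> phylogenetic
signal -> null models (betaNTI + RC_bray) -> process classification ->
spatial (PCNM, VIF, partial Mantel) -> network (+ per-sample subgraph
decay). A single global seed is expanded deterministically into per-stage
seeds; the same configuration and seed always produce an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, beta, diversity, io, network, spatial
from .simulate import SimulationConfig, simulate_metacommunity

logger = logging.getLogger(__name__)

STAGES = (
    "rarefy",
    "alpha",
    "beta",
    "signal",
    "nullmodel",
    "spatial",
    "network",
)

#: offsets into the expanded seed stream, one slot per stage
_STAGE_SEED_SLOTS = {name: i for i, name in enumerate(("simulate",) + STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    state = np.random.SeedSequence(int(global_seed)).generate_state(
        len(_STAGE_SEED_SLOTS)
    )
    return int(state[_STAGE_SEED_SLOTS[stage]] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def load_config(config_path: str | Path) -> dict:
    with open(config_path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    return config


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None) -> dict:
    """Run the configured stages and write stage outputs plus report.json.

    ``config`` is a YAML path or an equivalent dict with keys: ``seed``
    (required), ``outdir``, either ``simulate`` (a
    :class:`~assemblage.simulate.SimulationConfig` mapping) or ``inputs``
    (paths: otu_table, tree, metadata, optional taxonomy), optional
    ``stages`` (subset to run) and per-stage parameter mappings.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if "seed" not in config:
        raise ValueError("config requires a 'seed'")
    seed = int(config["seed"])
    outdir = Path(outdir or config.get("outdir", "assemblage_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(config.get("stages", STAGES))
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    report: dict = {
        "seed": seed,
        "stages": {},
        "thresholds": {
            "bnti": assembly.BNTI_THRESHOLD,
            "rc_bray": assembly.RC_THRESHOLD,
        },
        "outputs": {},
    }

    def stage_enabled(name: str) -> bool:
        return name in requested

    def record(name: str, status: str, t0: float | None = None, **extra):
        entry = {"status": status, **extra}
        report["stages"][name] = entry
        if t0 is not None:
            logger.info("stage %s: %s (%.2fs)", name, status, time.time() - t0)

    # ---- load or simulate -------------------------------------------------
    t0 = time.time()
    taxonomy = None
    if "simulate" in config:
        sim_params = dict(config["simulate"])
        sim_params.setdefault("seed", stage_seed(seed, "simulate"))
        sim_config = SimulationConfig(**sim_params)
        dataset = simulate_metacommunity(sim_config)
        table, phylogeny, metadata, taxonomy = (
            dataset.table,
            dataset.phylogeny,
            dataset.metadata,
            dataset.taxonomy,
        )
        io.write_otu_table(table, outdir / "otu_table.tsv")
        io.write_tree(phylogeny, outdir / "tree.nwk")
        io.write_metadata(metadata, outdir / "metadata.tsv")
        io.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        record(
            "input", "simulated",
            true_regime=dataset.true_regime,
            n_samples=table.shape[0], n_otus=table.shape[1],
        )
        report["input_hashes"] = {
            name: _sha256(outdir / name)
            for name in ("otu_table.tsv", "tree.nwk", "metadata.tsv", "taxonomy.tsv")
        }
    elif "inputs" in config:
        paths = config["inputs"]
        for key in ("otu_table", "metadata"):
            if key not in paths:
                raise ValueError(f"inputs missing {key!r}")
        if "tree" not in paths:
            tree_stages = [
                s for s in ("alpha", "signal", "nullmodel") if stage_enabled(s)
            ]
            detail = (
                f", required by stages: {tree_stages}" if tree_stages else ""
            )
            raise ValueError(f"inputs missing 'tree'{detail}")
        bundle = io.load_inputs(
            paths["otu_table"],
            paths["tree"],
            paths["metadata"],
            paths.get("taxonomy"),
        )
        table, phylogeny, metadata, taxonomy = (
            bundle.table,
            bundle.phylogeny,
            bundle.metadata,
            bundle.taxonomy,
        )
        record("input", "loaded", n_samples=table.shape[0], n_otus=table.shape[1])
        report["input_hashes"] = {
            key: _sha256(Path(p)) for key, p in paths.items()
        }
    else:
        raise ValueError("config requires either 'simulate' or 'inputs'")

    # ---- rarefy -----------------------------------------------------------
    if stage_enabled("rarefy"):
        t0 = time.time()
        params = dict(config.get("rarefy", {}))
        depth = int(params.get("depth", table.sample_totals().min()))
        table = diversity.rarefy(table, depth, stage_seed(seed, "rarefy"))
        metadata = metadata.align_to(table.sample_ids)
        io.write_otu_table(table, outdir / "otu_table.rarefied.tsv")
        record("rarefy", "ok", t0, depth=depth, n_samples=table.shape[0])
    else:
        record("rarefy", "skipped")

    # ---- alpha ------------------------------------------------------------
    if stage_enabled("alpha"):
        t0 = time.time()
        alpha = diversity.alpha_diversity(table, phylogeny)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        record(
            "alpha", "ok", t0,
            mean_shannon=float(alpha["shannon"].mean()),
            mean_goods_coverage=float(alpha["goods_coverage"].mean()),
        )
    else:
        record("alpha", "skipped")

    # ---- beta + decay -----------------------------------------------------
    geo = beta.geographic_distance(metadata)
    bc = None
    if stage_enabled("beta"):
        t0 = time.time()
        params = dict(config.get("beta", {}))
        n_perm = int(params.get("n_permutations", 999))
        bc = beta.bray_curtis(table)
        io.write_distance_matrix(bc, outdir / "bray_curtis.tsv")
        io.write_distance_matrix(geo, outdir / "geographic_km.tsv")
        s_beta = stage_seed(seed, "beta")
        decay = beta.distance_decay(bc, geo, n_perm, s_beta)
        decay_rows = [
            {
                "clade": "all",
                "rho": decay.rho,
                "p_value": decay.p_value,
                "n_pairs": decay.n_pairs,
            }
        ]
        if taxonomy is not None:
            for clade in taxonomy.clades:
                try:
                    result = beta.clade_distance_decay(
                        table, taxonomy, clade, metadata, n_perm, s_beta
                    )
                except (ValueError, KeyError) as exc:
                    logger.warning("clade %s decay skipped: %s", clade, exc)
                    continue
                decay_rows.append(
                    {
                        "clade": clade,
                        "rho": result.rho,
                        "p_value": result.p_value,
                        "n_pairs": result.n_pairs,
                    }
                )
        decay_df = pd.DataFrame(decay_rows)
        decay_df.to_csv(outdir / "distance_decay.tsv", sep="\t", index=False)
        occ_records, occ_rho, occ_p = beta.abundance_occupancy(
            table, n_perm, s_beta
        )
        occ_records.to_csv(
            outdir / "abundance_occupancy.tsv", sep="\t", index_label="otu_id"
        )
        extra = {}
        if "season" in metadata.data.columns:
            seasons = metadata.data["season"]
            if seasons.nunique() == 2 and (seasons.value_counts() >= 2).all():
                result = beta.permanova(bc, seasons, n_perm, s_beta)
                extra["permanova_season"] = {
                    "pseudo_f": result.pseudo_f,
                    "r2": result.r2,
                    "p_value": result.p_value,
                }
        record(
            "beta", "ok", t0,
            decay_rho=decay.rho, decay_p=decay.p_value,
            abundance_occupancy_rho=occ_rho,
            abundance_occupancy_p=occ_p,
            **extra,
        )
    else:
        record("beta", "skipped")

    # ---- phylogenetic signal ---------------------------------------------
    if stage_enabled("signal"):
        t0 = time.time()
        params = dict(config.get("signal", {}))
        optima = assembly.niche_optima(
            table, metadata, params.get("variables")
        )
        phylo_dm = assembly.cophenetic_distances(
            phylogeny.prune_to(table.otu_ids)
        )
        correlogram = assembly.phylogenetic_signal_correlogram(
            optima,
            phylo_dm,
            n_classes=int(params.get("n_classes", 10)),
            n_permutations=int(params.get("n_permutations", 199)),
            seed=stage_seed(seed, "signal"),
        )
        correlogram.to_csv(outdir / "phylo_signal.tsv", sep="\t", index=False)
        first = correlogram.iloc[0]
        record(
            "signal", "ok", t0,
            first_class_r=float(first["mantel_r"]),
            first_class_significant=bool(first["significant"]),
        )
    else:
        record("signal", "skipped")
        phylo_dm = None

    # ---- null models + classification -------------------------------------
    if stage_enabled("nullmodel"):
        t0 = time.time()
        params = dict(config.get("nullmodel", {}))
        result = assembly.assembly_analysis(
            table,
            phylogeny.prune_to(table.otu_ids),
            n_null=int(params.get("n_null", 999)),
            seed=stage_seed(seed, "nullmodel"),
            weighted=bool(params.get("weighted", True)),
        )
        result.pairs.to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False)
        fractions = result.fractions.as_dict()
        with open(outdir / "process_fractions.json", "w") as handle:
            json.dump(_round_floats(fractions), handle, indent=2, sort_keys=True)
        plurality = max(
            result.fractions.fractions, key=result.fractions.fractions.get
        )
        record(
            "nullmodel", "ok", t0,
            process_fractions=fractions,
            plurality_process=plurality,
        )
    else:
        record("nullmodel", "skipped")

    # ---- spatial corroboration --------------------------------------------
    if stage_enabled("spatial"):
        t0 = time.time()
        params = dict(config.get("spatial", {}))
        axes = spatial.pcnm(geo)
        axes.axes.to_csv(outdir / "pcnm_axes.tsv", sep="\t", index_label="sample_id")
        env = metadata.env_matrix(params.get("variables"))
        retained, vifs = spatial.vif_filter(
            env, float(params.get("vif_threshold", 10.0))
        )
        spatial_dm = spatial.pcnm_distance(axes)
        env_z = (env[retained] - env[retained].mean()) / env[retained].std(ddof=1)
        from scipy.spatial.distance import pdist, squareform
        import skbio as _skbio

        env_dm = _skbio.DistanceMatrix(
            squareform(pdist(env_z.to_numpy())), ids=list(env.index)
        )
        if bc is None:
            bc = beta.bray_curtis(table)
        s_spatial = stage_seed(seed, "spatial")
        n_perm = int(params.get("n_permutations", 999))
        space_given_env = spatial.partial_mantel(
            bc, spatial_dm, env_dm, "spearman", n_perm, s_spatial
        )
        env_given_space = spatial.partial_mantel(
            bc, env_dm, spatial_dm, "spearman", n_perm, s_spatial
        )
        record(
            "spatial", "ok", t0,
            n_pcnm_axes=int(axes.axes.shape[1]),
            retained_variables=retained,
            vif={k: float(v) for k, v in vifs.items()},
            partial_mantel_space={"r": space_given_env.r, "p": space_given_env.p_value},
            partial_mantel_env={"r": env_given_space.r, "p": env_given_space.p_value},
        )
    else:
        record("spatial", "skipped")

    # ---- network -----------------------------------------------------------
    if stage_enabled("network"):
        t0 = time.time()
        params = dict(config.get("network", {}))
        filtered = network.filter_otus(
            table,
            float(params.get("min_mean_ra", 0.0001)),
            float(params.get("min_occurrence", 0.2)),
        )
        graph = network.build_network(
            filtered,
            float(params.get("r_threshold", 0.7)),
            float(params.get("p_threshold", 0.01)),
            taxonomy=taxonomy,
        )
        extra: dict = {"n_filtered_otus": filtered.shape[1]}
        if graph.number_of_nodes() == 0:
            record("network", "empty", t0, **extra)
        else:
            network.assign_modules(graph)
            network.write_graphml(graph, outdir / "network.graphml")
            network.write_edgelist(graph, outdir / "network_edges.tsv")
            features = network.topology(graph)
            node_table = network.node_metrics(graph)
            node_table.to_csv(outdir / "node_metrics.tsv", sep="\t", index_label="otu_id")
            pd.DataFrame([features.as_series()]).to_csv(
                outdir / "network_topology.tsv", sep="\t", index=False
            )
            extra["topology"] = {
                k: v for k, v in features.as_series().items()
            }
            try:
                sub_features = network.sample_topology_table(graph, filtered)
                sub_features.to_csv(
                    outdir / "subgraph_topology.tsv", sep="\t",
                    index_label="sample_id",
                )
                decay = network.topology_decay(
                    sub_features,
                    geo,
                    int(params.get("n_permutations", 999)),
                    stage_seed(seed, "network"),
                )
                extra["topology_decay"] = {"r": decay.r, "p": decay.p_value}
            except ValueError as exc:
                logger.warning("subgraph topology decay not testable: %s", exc)
                extra["topology_decay"] = None
            record("network", "ok", t0, **extra)
    else:
        record("network", "skipped")

    report = _round_floats(report)
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report
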