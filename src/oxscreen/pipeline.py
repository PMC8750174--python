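"""End-to-end orchestration of the five analysis stages.

A single configuration (YAML/JSON mapping) drives either a fully synthetic
run (a ``simulation`` block with a mandatory seed) or a run over real input
files (an ``inputs`` block).  Stage outputs land under one run directory and
a manifest records the configuration hash and a content hash of every output
file, so any stage can be re-run independently from prior outputs.

Default thresholds encode the screen's published procedure: shell-1 and
shell-2 interaction scores 900 (very high confidence), relaxed score 700
(high confidence), adjusted-p cutoff 0.05, kappa threshold 0.5, and the
five-bin effect-size classification.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

from . import (
    drug_mining,
    enrichment,
    ppi_network,
    screen_stats,
    synthetic_data,
    target_catalog,
)
from .exceptions import ConfigError, PipelineError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "shell1_score": 900,
    "shell2_score": 900,
    "relaxed_score": 700,
    "adj_p_cutoff": 0.05,
    "kappa_threshold": 0.5,
}

DEFAULT_SIMULATION = {
    "screen": {
        "n_sirnas": 30,
        "replicates": 20,
        "timepoints": 6,
        "noise_sd": 10.0,
        "bin_centers": list(synthetic_data.DEFAULT_BIN_CENTERS),
    },
    "blast": {"n_genes": 120, "n_queries": 25, "decoys_per_query": 3},
    "interactome": {
        "module_sizes": [8, 5, 3],
        "n_background": 20,
        "p_within": 1.0,
        "score_range": [41, 998],
    },
    "genesets": {
        "universe_size": 400,
        "n_sets": 25,
        "set_size_range": [10, 40],
        "planted_set_overlap": 15,
        "query_size": 30,
    },
    "drugs": {
        "n_common_drugs": 5,
        "n_cross_db_common": 3,
        "approved_fraction": 0.6,
        "n_extra_per_list": 4,
    },
}

INPUT_KEYS = (
    "plate_csv",
    "blast_tsv",
    "annotation_tsv",
    "interactions_tsv",
    "gmt",
    "query_genes",
    "targets_file",
    "genes_a",
    "genes_b",
    "drug_db_tsv",
    "drug_ttd_tsv",
)


def validate_config(config: dict) -> tuple[dict, list[str]]:
    """Normalize a configuration, filling defaults; report every violation.

    Returns (normalized config, error list).  Does not raise: callers decide
    whether errors are fatal.
    """
    cfg = copy.deepcopy(config) if config else {}
    errors: list[str] = []

    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for key in ("shell1_score", "shell2_score", "relaxed_score"):
        value = thresholds[key]
        if not (ppi_network.SCORE_MIN <= value <= ppi_network.SCORE_MAX):
            errors.append(
                f"thresholds.{key}={value} outside "
                f"[{ppi_network.SCORE_MIN}, {ppi_network.SCORE_MAX}]"
            )
    if not (0 < thresholds["adj_p_cutoff"] < 1):
        errors.append(f"thresholds.adj_p_cutoff={thresholds['adj_p_cutoff']} not in (0, 1)")
    if not (0 <= thresholds["kappa_threshold"] <= 1):
        errors.append(
            f"thresholds.kappa_threshold={thresholds['kappa_threshold']} not in [0, 1]"
        )
    cfg["thresholds"] = thresholds

    has_sim = "simulation" in cfg
    has_inputs = "inputs" in cfg
    if not has_sim and not has_inputs:
        errors.append("config needs a 'simulation' block or an 'inputs' block")
    if has_sim:
        sim = cfg["simulation"]
        if "seed" not in sim:
            errors.append("simulation.seed is mandatory (no wall-clock seeding)")
        merged = {}
        for stage, defaults in DEFAULT_SIMULATION.items():
            merged[stage] = {**defaults, **sim.get(stage, {})}
        merged["seed"] = sim.get("seed")
        cfg["simulation"] = merged
    if has_inputs:
        missing = [k for k in INPUT_KEYS if k not in cfg["inputs"]]
        if missing and not has_sim:
            errors.append(f"inputs block missing paths: {missing}")

    if "output_dir" not in cfg:
        errors.append("output_dir is required")
    return cfg, errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    return wrap


def _simulate_inputs(cfg: dict, out: Path) -> dict:
    sim = cfg["simulation"]
    seed = int(sim["seed"])
    inputs_dir = out / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    plate, screen_truth = synthetic_data.simulate_screen(seed=seed, **sim["screen"])
    paths["plate_csv"] = inputs_dir / "plate.csv"
    synthetic_data.write_plate_csv(plate, paths["plate_csv"])
    screen_truth.to_json(inputs_dir / "truth_screen.json")

    hits, ann, blast_truth = synthetic_data.simulate_hits_and_annotation(
        seed=seed + 1, **sim["blast"]
    )
    paths["blast_tsv"] = inputs_dir / "blast_hits.tsv"
    paths["annotation_tsv"] = inputs_dir / "annotation.tsv"
    synthetic_data.write_blast_tsv(hits, paths["blast_tsv"])
    synthetic_data.write_annotation_tsv(ann, paths["annotation_tsv"])
    blast_truth.to_json(inputs_dir / "truth_blast.json")

    interactions, net_truth = synthetic_data.simulate_interactome(
        seed=seed + 2, **sim["interactome"]
    )
    paths["interactions_tsv"] = inputs_dir / "interactions.tsv"
    synthetic_data.write_interactions_tsv(interactions, paths["interactions_tsv"])
    net_truth.to_json(inputs_dir / "truth_interactome.json")
    module_nodes = sorted({n for m in net_truth.planted_modules for n in m})
    paths["targets_file"] = inputs_dir / "network_targets.txt"
    synthetic_data.write_gene_list(module_nodes, paths["targets_file"])

    sets, query, set_truth = synthetic_data.simulate_genesets(
        seed=seed + 3, **sim["genesets"]
    )
    paths["gmt"] = inputs_dir / "collection.gmt"
    enrichment.write_gmt(sets, paths["gmt"])
    paths["query_genes"] = inputs_dir / "query_genes.txt"
    synthetic_data.write_gene_list(query, paths["query_genes"])
    set_truth.to_json(inputs_dir / "truth_genesets.json")

    genes_a = [f"DGA{i:03d}" for i in range(1, 13)]
    genes_b = [f"DGB{i:03d}" for i in range(1, 13)]
    db, ttd, drug_truth = synthetic_data.simulate_drug_tables(
        genes_a, genes_b, seed=seed + 4, **sim["drugs"]
    )
    paths["genes_a"] = inputs_dir / "drug_genes_a.txt"
    paths["genes_b"] = inputs_dir / "drug_genes_b.txt"
    synthetic_data.write_gene_list(genes_a, paths["genes_a"])
    synthetic_data.write_gene_list(genes_b, paths["genes_b"])
    paths["drug_db_tsv"] = inputs_dir / "drugs_db.tsv"
    paths["drug_ttd_tsv"] = inputs_dir / "drugs_ttd.tsv"
    synthetic_data.write_drug_tsv(db, paths["drug_db_tsv"])
    synthetic_data.write_drug_tsv(ttd, paths["drug_ttd_tsv"])
    drug_truth.to_json(inputs_dir / "truth_drugs.json")
    return paths


def run_pipeline(config: dict) -> dict:
    """Run every stage from one configuration; returns the manifest dict.

    Any stage failure raises :class:`PipelineError` naming the stage; outputs
    written before the failure are retained.
    """
    cfg, errors = validate_config(config)
    if errors:
        raise ConfigError(errors)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log_handler = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(log_handler)

    try:
        if "simulation" in cfg:
            paths = _stage("simulate")(_simulate_inputs, cfg, out)
        else:
            paths = {k: Path(v) for k, v in cfg["inputs"].items()}
        thr = cfg["thresholds"]

        # screen statistics
        def screen_stage():
            plate = screen_stats.read_plate_csv(paths["plate_csv"])
            effects = screen_stats.effect_sizes(plate, synthetic_data.NEGATIVE_CONTROL)
            screen_stats.write_effects_tsv(effects, out / "effect_sizes.tsv")
            counts = {
                str(tp): screen_stats.summarize_screen(effects, tp)
                for tp in sorted(effects["timepoint_h"].unique())
            }
            with open(out / "bin_counts.json", "w") as fh:
                json.dump(counts, fh, indent=2, sort_keys=True)
                fh.write("\n")
            return effects

        effects = _stage("screen_stats")(screen_stage)

        # target catalog
        def catalog_stage():
            hits = target_catalog.parse_blast_tabular(paths["blast_tsv"])
            ann = target_catalog.read_annotation_tsv(paths["annotation_tsv"])
            per_query = target_catalog.dedupe_symbols(
                target_catalog.annotate_and_prune(
                    target_catalog.best_hits_per_query(
                        target_catalog.filter_accession_prefix(hits)
                    ),
                    ann,
                )
            )
            catalog = target_catalog.build_catalog(per_query)
            target_catalog.write_catalog_tsv(per_query, out / "target_catalog.tsv")
            target_catalog.write_tally_json(catalog, out / "catalog_tally.json")
            return catalog

        catalog = _stage("target_catalog")(catalog_stage)

        # PPI networks
        def network_stage():
            edges = ppi_network.load_interactions(paths["interactions_tsv"])
            targets = set(synthetic_data.read_gene_list(paths["targets_file"]))
            flag_file = cfg.get("inputs", {}).get("flag_genes")
            flags = set(synthetic_data.read_gene_list(flag_file)) if flag_file else set()
            builds = {
                "targets_only": dict(shells=0, t1=thr["shell1_score"]),
                "shell1_very_high": dict(shells=1, t1=thr["shell1_score"]),
                "shell1_high": dict(shells=1, t1=thr["relaxed_score"]),
                "shell2_very_high": dict(
                    shells=2, t1=thr["shell1_score"], t2=thr["shell2_score"]
                ),
            }
            summaries = {}
            for name, params in builds.items():
                net = ppi_network.expand_network(targets, edges, **params)
                ppi_network.write_network(
                    net, out / f"network_{name}_edges.tsv", out / f"network_{name}_roles.tsv"
                )
                summaries[name] = ppi_network.summarize_network(net, targets, flags)
            ppi_network.write_summary_json(summaries, out / "network_summaries.json")
            return summaries

        summaries = _stage("ppi_network")(network_stage)

        # enrichment + clustering
        def enrich_stage():
            collection = enrichment.read_gmt(paths["gmt"])
            query = synthetic_data.read_gene_list(paths["query_genes"])
            results = enrichment.run_ora(query, collection, alpha=thr["adj_p_cutoff"])
            enrichment.write_enrichment_tsv(results, out / "enrichment.tsv")
            clusters = enrichment.cluster_terms(
                results, collection, kappa_threshold=thr["kappa_threshold"]
            )
            enrichment.write_clusters_json(clusters, out / "term_clusters.json")
            return results, collection

        results, collection = _stage("enrichment")(enrich_stage)

        # drug mining
        def drug_stage():
            db = drug_mining.load_drug_table(paths["drug_db_tsv"], dialect="DB")
            ttd = drug_mining.load_drug_table(paths["drug_ttd_tsv"], dialect="TTD")
            genes_a = synthetic_data.read_gene_list(paths["genes_a"])
            genes_b = synthetic_data.read_gene_list(paths["genes_b"])
            report = drug_mining.DrugMiningReport()
            for label, genes in (("listA", genes_a), ("listB", genes_b)):
                report.hits[f"{label}_DB"] = drug_mining.query_drugs(genes, db)
                report.hits[f"{label}_TTD"] = drug_mining.query_drugs(genes, ttd)
            report.intersections["within_db_approved"] = sorted(
                drug_mining.intersect_hits(
                    report.hits["listA_DB"], report.hits["listB_DB"]
                )
            )
            both = drug_mining.query_drugs(genes_a + genes_b, db)
            both_ttd = drug_mining.query_drugs(genes_a + genes_b, ttd)
            report.intersections["cross_db_approved"] = drug_mining.cross_database_common(
                both, both_ttd
            )
            drug_mining.write_report_json(report, out / "drug_mining.json")
            coverage = drug_mining.pathway_drug_coverage(results, collection, db)
            coverage.to_csv(out / "pathway_drug_coverage.tsv", sep="\t", index=False)
            return report

        report = _stage("drug_mining")(drug_stage)

        manifest = _write_manifest(cfg, out)
        return manifest
    finally:
        logging.getLogger().removeHandler(log_handler)
        log_handler.close()


def _write_manifest(cfg: dict, out: Path) -> dict:
    from . import __version__

    config_text = json.dumps(cfg, sort_keys=True, default=str)
    files = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name not in ("manifest.json", "run.log"):
            files[str(path.relative_to(out))] = _sha256(path)
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": cfg.get("simulation", {}).get("seed"),
        "package_version": __version__,
        "outputs": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
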