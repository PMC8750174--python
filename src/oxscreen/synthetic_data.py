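"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one input kind of the screen-analysis pipeline —
plate viability readings, BLAST tabular hits with an annotation table, a
scored interactome, GMT gene-set collections, and drug-target tables in two
dialects — and records the planted truth (effects, best-hit targets,
connected modules, enriched sets, drug-overlap counts) so downstream stages
can be tested for exact or statistical recovery without any downloads.

All generators are fully determined by their seed: the same seed and
parameters yield byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .ppi_network import SCORE_MIN, SCORE_MAX
from .screen_stats import PLATE_COLUMNS
from .target_catalog import BIOTYPES, BLAST_COLUMNS

#: Canonical viability read times (hours after reagent addition).
READ_HOURS = (19, 24, 48, 72, 120, 144)

NEGATIVE_CONTROL = "neg_control"

#: Default planted standardized differences, one per effect-size bin
#: (large, medium, small, very_small, none).
DEFAULT_BIN_CENTERS = (1.2, 0.65, 0.35, 0.1, 0.0)


@dataclass
class SimulationTruth:
    """Planted ground truth accompanying a set of generated input files."""

    seed: int
    planted_effects: dict[str, float] = field(default_factory=dict)
    planted_targets: dict[str, int] = field(default_factory=dict)
    planted_modules: list[list[str]] = field(default_factory=list)
    planted_enriched_sets: list[dict] = field(default_factory=list)
    planted_drug_overlaps: dict[str, int] = field(default_factory=dict)
    planted_biotype_tally: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {value}")


def _timepoint_hours(timepoints: int) -> list[int]:
    hours = list(READ_HOURS[:timepoints])
    while len(hours) < timepoints:
        hours.append(hours[-1] + 24)
    return hours


def _unit_deviates(n: int) -> np.ndarray:
    """A deterministic vector with exactly zero sample mean and unit sample SD."""
    v = np.arange(n, dtype=float) - (n - 1) / 2.0
    return v / v.std(ddof=1)


def simulate_screen(
    n_sirnas: int,
    bin_centers=DEFAULT_BIN_CENTERS,
    replicates: int = 4,
    timepoints: int = 6,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate plate viability readings with planted standardized differences.

    The negative control reads 100 survival units on average; test siRNA *i*
    reads 100 + d_i * noise_sd with Gaussian noise of SD *noise_sd*, so its
    true Cohen's d against the control is exactly d_i.  Planted d values cycle
    through *bin_centers* (defaults put one siRNA per effect-size bin in
    turn).  Noise is homoscedastic across conditions and timepoints.

    ``noise_sd=0`` selects the deterministic limit: replicate deviates with
    exactly zero sample mean and unit sample SD around means 100 and
    100 + d_i, so the estimated Cohen's d equals the planted d exactly.

    Returns (plate reading table, truth).
    """
    _check_positive(n_sirnas=n_sirnas, replicates=replicates, timepoints=timepoints)
    if replicates < 2:
        raise InvalidParameterError("replicates must be >= 2")
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    bin_centers = list(bin_centers)
    if not bin_centers:
        raise InvalidParameterError("bin_centers must be non-empty")

    rng = np.random.default_rng(seed)
    hours = _timepoint_hours(timepoints)
    sirna_ids = [f"siRNA_{i+1:03d}" for i in range(n_sirnas)]
    planted = {sid: float(bin_centers[i % len(bin_centers)]) for i, sid in enumerate(sirna_ids)}

    exact = noise_sd == 0.0
    scale = 1.0 if exact else noise_sd
    unit = _unit_deviates(replicates)

    rows = []
    for cond in [NEGATIVE_CONTROL] + sirna_ids:
        d = 0.0 if cond == NEGATIVE_CONTROL else planted[cond]
        for tp in hours:
            if exact:
                readings = 100.0 + d * scale + unit
            else:
                readings = 100.0 + d * scale + rng.normal(0.0, noise_sd, replicates)
            for rep, reading in enumerate(readings, start=1):
                rows.append(
                    {
                        "condition": cond,
                        "sirna_id": "" if cond == NEGATIVE_CONTROL else cond,
                        "replicate": rep,
                        "timepoint_h": tp,
                        "reading": round(float(reading), 9),
                    }
                )
    table = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    truth = SimulationTruth(seed=seed, planted_effects=planted)
    return table, truth


_BIOTYPE_PREFIX = {
    "protein coding": "NM",
    "lncRNA": "NR",
    "pseudogene": "NR",
    "TEC": "XR",
}

#: Accession prefix excluded by the catalog reduction (genomic RefSeq class).
_DISALLOWED_PREFIX = "NG"


def simulate_hits_and_annotation(
    n_genes: int,
    biotype_mix=(0.94, 0.05, 0.007, 0.003),
    n_queries: int = 20,
    decoys_per_query: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate a BLAST hit table plus annotation with planted best-hit targets.

    Each query carries exactly one planted best hit — minimum E-value, allowed
    accession prefix, valid Entrez annotation — plus *decoys_per_query* decoy
    hits that each violate a reduction rule (disallowed accession prefix,
    annotation without an Entrez id, or a valid gene at a strictly higher
    E-value).  Decoy E-values exceed the planted best by at least one order of
    magnitude, so no accidental ties arise.

    *biotype_mix* gives proportions over (protein coding, lncRNA, pseudogene,
    TEC) and must sum to 1.  Returns (hits table, annotation table, truth).
    """
    _check_positive(n_genes=n_genes, n_queries=n_queries)
    if decoys_per_query < 0:
        raise InvalidParameterError("decoys_per_query must be >= 0")
    mix = np.asarray(biotype_mix, dtype=float)
    if len(mix) != len(BIOTYPES) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(
            f"biotype_mix must be {len(BIOTYPES)} non-negative proportions summing to 1"
        )
    if n_queries > n_genes:
        raise InvalidParameterError("need n_genes >= n_queries for distinct targets")

    rng = np.random.default_rng(seed)
    biotypes = [BIOTYPES[i] for i in rng.choice(len(BIOTYPES), size=n_genes, p=mix)]
    genes = []
    for i in range(n_genes):
        bt = biotypes[i]
        genes.append(
            {
                "entrez_id": 100000 + i,
                "symbol": f"GENE{i+1:05d}",
                "biotype": bt,
                "accession": f"{_BIOTYPE_PREFIX[bt]}_{700000 + i:06d}.1",
            }
        )

    ann_rows = [dict(g) for g in genes]
    hit_rows = []
    target_idx = rng.choice(n_genes, size=n_queries, replace=False)
    planted_targets: dict[str, int] = {}
    decoy_serial = 0
    for q in range(n_queries):
        query_id = f"siRNA_{q+1:03d}"
        gene = genes[int(target_idx[q])]
        planted_targets[query_id] = gene["entrez_id"]
        best_e = 10.0 ** rng.uniform(-30, -2)
        hit_rows.append(_blast_row(query_id, gene["accession"], best_e, rng))
        for j in range(decoys_per_query):
            decoy_e = best_e * 10.0 ** rng.uniform(1, 6)
            kind = j % 3
            decoy_serial += 1
            if kind == 0:  # disallowed accession prefix, annotated normally
                acc = f"{_DISALLOWED_PREFIX}_{800000 + decoy_serial:06d}.1"
                ann_rows.append(
                    {
                        "entrez_id": 900000 + decoy_serial,
                        "symbol": f"DECOY{decoy_serial:05d}",
                        "biotype": "protein coding",
                        "accession": acc,
                    }
                )
            elif kind == 1:  # allowed prefix but annotation lacks an Entrez id
                acc = f"XM_{810000 + decoy_serial:06d}.1"
                ann_rows.append(
                    {
                        "entrez_id": None,
                        "symbol": f"NOENTREZ{decoy_serial:05d}",
                        "biotype": "protein coding",
                        "accession": acc,
                    }
                )
            else:  # valid gene, strictly higher E-value
                other = genes[int(rng.integers(n_genes))]
                acc = other["accession"]
            hit_rows.append(_blast_row(query_id, acc, decoy_e, rng))

    hits = pd.DataFrame(hit_rows, columns=BLAST_COLUMNS)
    annotation = pd.DataFrame(
        ann_rows, columns=["accession", "entrez_id", "symbol", "biotype"]
    )
    annotation["entrez_id"] = annotation["entrez_id"].astype("Int64")
    tally: dict[str, int] = {}
    for entrez in set(planted_targets.values()):
        bt = genes[entrez - 100000]["biotype"]
        tally[bt] = tally.get(bt, 0) + 1
    truth = SimulationTruth(
        seed=seed, planted_targets=planted_targets, planted_biotype_tally=tally
    )
    return hits, annotation, truth


def _blast_row(query_id: str, accession: str, e_value: float, rng) -> dict:
    length = int(rng.integers(18, 22))
    return {
        "qseqid": query_id,
        "sseqid": accession,
        "pident": round(float(rng.uniform(85, 100)), 2),
        "length": length,
        "mismatch": int(rng.integers(0, 3)),
        "gapopen": 0,
        "qstart": 1,
        "qend": length,
        "sstart": 100,
        "send": 100 + length - 1,
        "evalue": float(f"{e_value:.3e}"),
        "bitscore": round(float(rng.uniform(30, 45)), 1),
    }


def simulate_interactome(
    module_sizes=(8, 5, 3),
    n_background: int = 20,
    score_range: tuple[int, int] = (SCORE_MIN, SCORE_MAX),
    p_within: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a scored interaction table with planted connected modules.

    Each planted module is internally connected at the top of *score_range*
    (a random spanning tree plus extra within-module pairs with probability
    *p_within*); background nodes attach sparsely in disjoint pairs at the
    bottom of the range.  ``p_within=0`` suppresses module edges entirely, so
    no component exceeds two nodes.  Every unordered pair appears at most
    once.

    Returns (interaction table with columns protein1/protein2/combined_score,
    truth with the planted module node sets).
    """
    lo, hi = int(score_range[0]), int(score_range[1])
    if not (SCORE_MIN <= lo <= hi <= SCORE_MAX):
        raise InvalidParameterError(
            f"score_range must lie within [{SCORE_MIN}, {SCORE_MAX}], got {score_range}"
        )
    if not 0.0 <= p_within <= 1.0:
        raise InvalidParameterError("p_within must be a probability")
    if n_background < 0:
        raise InvalidParameterError("n_background must be >= 0")
    for size in module_sizes:
        if size < 1:
            raise InvalidParameterError("module sizes must be >= 1")

    rng = np.random.default_rng(seed)
    edges: dict[tuple[str, str], int] = {}

    def add_edge(a: str, b: str, score: int) -> None:
        key = (a, b) if a < b else (b, a)
        edges.setdefault(key, score)

    modules: list[list[str]] = []
    for m, size in enumerate(module_sizes, start=1):
        nodes = [f"MOD{m}_{i+1:02d}" for i in range(size)]
        modules.append(nodes)
        if p_within > 0 and size > 1:
            order = list(rng.permutation(nodes))
            for i in range(1, size):  # random spanning tree keeps the module connected
                parent = order[int(rng.integers(i))]
                add_edge(order[i], parent, hi)
            for i in range(size):
                for j in range(i + 1, size):
                    if rng.random() < p_within:
                        add_edge(nodes[i], nodes[j], hi)

    background = [f"BG_{i+1:03d}" for i in range(n_background)]
    for i in range(0, n_background - 1, 2):  # disjoint low-score pairs
        add_edge(background[i], background[i + 1], lo)

    rows = [
        {"protein1": a, "protein2": b, "combined_score": score}
        for (a, b), score in sorted(edges.items())
    ]
    table = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    truth = SimulationTruth(seed=seed, planted_modules=[sorted(m) for m in modules])
    return table, truth


def simulate_genesets(
    universe_size: int = 500,
    n_sets: int = 25,
    set_size_range: tuple[int, int] = (10, 40),
    planted_set_overlap: int = 15,
    query_size: int = 30,
    seed: int = 0,
) -> tuple[list, list[str], SimulationTruth]:
    """Simulate a gene-set collection plus a query list with one enriched set.

    Exactly one planted set shares *planted_set_overlap* genes with the query;
    all other sets are uniform draws from the universe, so their query overlap
    is hypergeometric-random.  Returns (GeneSet list, query gene list, truth).
    """
    from .enrichment import GeneSet

    _check_positive(universe_size=universe_size, n_sets=n_sets, query_size=query_size)
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= universe_size):
        raise InvalidParameterError(f"bad set_size_range {set_size_range}")
    if query_size > universe_size:
        raise InvalidParameterError("query_size exceeds universe_size")
    if planted_set_overlap > min(query_size, hi):
        raise InvalidParameterError(
            "planted_set_overlap exceeds query size or maximum set size"
        )

    rng = np.random.default_rng(seed)
    universe = [f"G{i+1:05d}" for i in range(universe_size)]
    query = sorted(rng.choice(universe, size=query_size, replace=False))
    non_query = sorted(set(universe) - set(query))

    sets = []
    planted_id = "SET_0001"
    for s in range(n_sets):
        set_id = f"SET_{s+1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if set_id == planted_id:
            size = max(size, planted_set_overlap)
            inside = list(rng.choice(query, size=planted_set_overlap, replace=False))
            outside = list(
                rng.choice(non_query, size=size - planted_set_overlap, replace=False)
            )
            genes = frozenset(inside + outside)
        else:
            genes = frozenset(rng.choice(universe, size=size, replace=False))
        sets.append(GeneSet(set_id=set_id, name=f"synthetic set {s+1}", genes=genes))

    truth = SimulationTruth(
        seed=seed,
        planted_enriched_sets=[
            {"set_id": planted_id, "overlap": planted_set_overlap}
        ],
    )
    return sets, query, truth


def simulate_drug_tables(
    gene_list_a,
    gene_list_b,
    n_common_drugs: int = 5,
    n_cross_db_common: int = 3,
    approved_fraction: float = 0.6,
    n_extra_per_list: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate DB- and TTD-dialect drug-target tables with planted overlaps.

    Exactly *n_common_drugs* approved drugs target genes in both lists within
    the DB table; exactly *n_cross_db_common* approved drugs appear, by
    normalized name, in both tables (targeting genes in list A only, so they
    never inflate the within-DB A/B intersection).  Extra single-list drugs
    are approved with probability *approved_fraction*.

    Returns (DB table, TTD table, truth with the planted counts).
    """
    gene_list_a, gene_list_b = sorted(set(gene_list_a)), sorted(set(gene_list_b))
    if not gene_list_a or not gene_list_b:
        raise InvalidParameterError("both gene lists must be non-empty")
    if set(gene_list_a) & set(gene_list_b):
        raise InvalidParameterError("gene lists must be disjoint")
    if not 0.0 <= approved_fraction <= 1.0:
        raise InvalidParameterError("approved_fraction must be a proportion")
    for name, v in {
        "n_common_drugs": n_common_drugs,
        "n_cross_db_common": n_cross_db_common,
        "n_extra_per_list": n_extra_per_list,
    }.items():
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0")

    rng = np.random.default_rng(seed)
    db_rows, ttd_rows = [], []

    def pick(genes) -> str:
        return genes[int(rng.integers(len(genes)))]

    serial = 0
    for i in range(n_common_drugs):
        serial += 1
        drug_id, name = f"DB{serial:05d}", f"commondrug{i+1}"
        db_rows.append((drug_id, name, "approved", pick(gene_list_a)))
        db_rows.append((drug_id, name, "approved", pick(gene_list_b)))
    for i in range(n_cross_db_common):
        serial += 1
        name = f"crossdrug{i+1}"
        gene = pick(gene_list_a)
        db_rows.append((f"DB{serial:05d}", name, "approved", gene))
        ttd_rows.append((f"D{serial:05d}T", name.upper(), "Approved", gene))
    for listed, tag in ((gene_list_a, "a"), (gene_list_b, "b")):
        for i in range(n_extra_per_list):
            serial += 1
            status = "approved" if rng.random() < approved_fraction else "investigational"
            db_rows.append(
                (f"DB{serial:05d}", f"extra{tag}{i+1}", status, pick(listed))
            )
    for i in range(n_extra_per_list):
        serial += 1
        status = "Approved" if rng.random() < approved_fraction else "Patented"
        ttd_rows.append(
            (f"D{serial:05d}T", f"ttdonly{i+1}", status, pick(gene_list_b))
        )

    db = pd.DataFrame(db_rows, columns=["drug_id", "name", "group", "gene"])
    ttd = pd.DataFrame(ttd_rows, columns=["drug_code", "name", "status", "gene"])
    truth = SimulationTruth(
        seed=seed,
        planted_drug_overlaps={
            "common_within_db": n_common_drugs,
            "cross_db_common": n_cross_db_common,
        },
    )
    return db, ttd, truth


# --- file writers -----------------------------------------------------------


def write_plate_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_blast_tsv(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False, header=False)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_interactions_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_drug_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
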