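"""Cross-reference gene lists with drug-target tables for repurposing leads.

Two tabular dialects are consumed and normalized to one record schema:
a DrugBank-like table (drug_id, name, group, gene) and a TTD-like table
(drug_code, name, status, gene).  Mining reports, per gene list and source,
the target genes hit and distinct drugs with approved/patented breakdowns;
intersections between two hit sets (by drug id within one source) and between
databases (by normalized drug name, since codes differ across databases).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ParseError

logger = logging.getLogger(__name__)

STATUSES = ("approved", "patented", "other")

#: Tokens mapped to the closed status vocabulary (case-insensitive).
_STATUS_MAP = {
    "approved": "approved",
    "patented": "patented",
    "patented recorded": "patented",
    # known development-stage tokens outside the approved/patented dichotomy
    "investigational": "other",
    "experimental": "other",
    "clinical trial": "other",
    "withdrawn": "other",
    "illicit": "other",
    "nutraceutical": "other",
    "vet_approved": "other",
    "terminated": "other",
    "discontinued": "other",
}

_DIALECT_COLUMNS = {
    "DB": ["drug_id", "name", "group", "gene"],
    "TTD": ["drug_code", "name", "status", "gene"],
}


@dataclass(frozen=True)
class DrugTargetRecord:
    drug_id: str
    drug_name: str
    status: str
    gene: str
    source: str


@dataclass
class DrugHits:
    """Result of mining one gene list against one source's records."""

    source: str
    genes_hit: set
    drugs: dict[str, tuple[str, str]]  # drug_id -> (name, status)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def ids_with_status(self, status: str) -> set:
        return {d for d, (_, s) in self.drugs.items() if s == status}

    @property
    def n_approved(self) -> int:
        return len(self.ids_with_status("approved"))

    @property
    def n_patented(self) -> int:
        return len(self.ids_with_status("patented"))

    @property
    def pct_approved(self) -> float:
        return round(100.0 * self.n_approved / self.n_drugs, 1) if self.drugs else 0.0


def normalize_name(name: str) -> str:
    """Lowercase, trim, and collapse internal whitespace (cross-database identity)."""
    return re.sub(r"\s+", " ", name.strip().lower())


def map_status(token: str) -> str:
    """Map a raw group/status token to {approved, patented, other}."""
    status = _STATUS_MAP.get(str(token).strip().lower())
    if status is None:
        logger.warning("unknown drug status token %r mapped to 'other'", token)
        return "other"
    return status


def load_drug_table(path, dialect: str) -> list[DrugTargetRecord]:
    """Load a drug-target TSV in the DB or TTD dialect into the common schema.

    Unknown status tokens map to "other" with a warning; duplicate
    (drug, gene) rows collapse to one.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ParseError(f"unknown dialect {dialect!r}; expected 'DB' or 'TTD'")
    cols = _DIALECT_COLUMNS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(cols) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: {dialect} table missing columns {sorted(missing)}")
    id_col, status_col = cols[0], cols[2]
    records: dict[tuple[str, str], DrugTargetRecord] = {}
    for row in df.itertuples(index=False):
        rec = DrugTargetRecord(
            drug_id=getattr(row, id_col),
            drug_name=getattr(row, "name"),
            status=map_status(getattr(row, status_col)),
            gene=getattr(row, "gene"),
            source=dialect,
        )
        records[(rec.drug_id, rec.gene)] = rec
    return [records[k] for k in sorted(records)]


def query_drugs(genes, records: list[DrugTargetRecord]) -> DrugHits:
    """Mine a gene list against drug-target records.

    genes_hit are the query genes appearing as targets; drugs are the distinct
    drugs targeting at least one such gene (a drug hitting two query genes
    counts once).
    """
    genes = set(genes)
    sources = {r.source for r in records}
    if len(sources) > 1:
        raise ParseError(f"records mix sources {sorted(sources)}")
    genes_hit = set()
    drugs: dict[str, tuple[str, str]] = {}
    for r in records:
        if r.gene in genes:
            genes_hit.add(r.gene)
            drugs[r.drug_id] = (r.drug_name, r.status)
    return DrugHits(
        source=sources.pop() if sources else "", genes_hit=genes_hit, drugs=drugs
    )


def intersect_hits(hits_a: DrugHits, hits_b: DrugHits, status_filter: str = "approved") -> set:
    """Drugs (by drug_id, within one source) present in both hit sets.

    ``status_filter`` restricts to one status ("approved" by default) or
    "any".  Symmetric in its operands.
    """
    if status_filter == "any":
        ids_a, ids_b = set(hits_a.drugs), set(hits_b.drugs)
    else:
        ids_a = hits_a.ids_with_status(status_filter)
        ids_b = hits_b.ids_with_status(status_filter)
    return ids_a & ids_b


def cross_database_common(
    db_hits: DrugHits, ttd_hits: DrugHits, status_filter: str = "approved"
) -> list[tuple[str, str, str]]:
    """Drugs shared between the two databases, matched by normalized name.

    Returns sorted (db_id, ttd_id, normalized name) triples; one pairing per
    name (smallest ids win if a name maps to several codes in one database).
    """

    def names_of(hits: DrugHits) -> dict[str, str]:
        out: dict[str, str] = {}
        ids = (
            set(hits.drugs)
            if status_filter == "any"
            else hits.ids_with_status(status_filter)
        )
        for drug_id in sorted(ids, reverse=True):
            out[normalize_name(hits.drugs[drug_id][0])] = drug_id
        return out

    db_names = names_of(db_hits)
    ttd_names = names_of(ttd_hits)
    common = sorted(set(db_names) & set(ttd_names))
    return [(db_names[n], ttd_names[n], n) for n in common]


def pathway_drug_coverage(
    enrichment: pd.DataFrame,
    collection,
    records: list[DrugTargetRecord],
    status_filter: str = "approved",
) -> pd.DataFrame:
    """Per significant pathway, the member genes that are drug targets.

    Returns a long DataFrame (set_id, gene, drug_id, drug_name, status), one
    row per (pathway, gene, drug); pathways whose members attract no drugs
    contribute zero rows.  A drug targeting genes in two pathways appears
    under both.
    """
    by_id = {s.set_id: s for s in collection}
    gene_drugs: dict[str, list[DrugTargetRecord]] = {}
    for r in records:
        if status_filter in ("any", r.status):
            gene_drugs.setdefault(r.gene, []).append(r)
    rows = []
    for set_id in sorted(enrichment.loc[enrichment["significant"], "set_id"]):
        for gene in sorted(by_id[set_id].genes):
            for r in gene_drugs.get(gene, []):
                rows.append(
                    {
                        "set_id": set_id,
                        "gene": gene,
                        "drug_id": r.drug_id,
                        "drug_name": r.drug_name,
                        "status": r.status,
                    }
                )
    return pd.DataFrame(
        rows, columns=["set_id", "gene", "drug_id", "drug_name", "status"]
    )


@dataclass
class DrugMiningReport:
    """Mining counts for several gene lists plus named intersections."""

    hits: dict[str, DrugHits] = field(default_factory=dict)
    intersections: dict[str, list] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "hits": {
                key: {
                    "source": h.source,
                    "genes_hit": len(h.genes_hit),
                    "drugs": h.n_drugs,
                    "approved": h.n_approved,
                    "pct_approved": h.pct_approved,
                    "patented": h.n_patented,
                }
                for key, h in sorted(self.hits.items())
            },
            "intersections": {
                key: sorted(v) if isinstance(v, set) else list(v)
                for key, v in sorted(self.intersections.items())
            },
        }


def write_report_json(report: DrugMiningReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=list)
        fh.write("\n")
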