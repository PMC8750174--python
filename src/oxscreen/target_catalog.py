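"""Reduce BLAST tabular hits to a per-siRNA target-gene catalog.

The reduction chain mirrors the homology-search post-processing of an RNAi
screen: keep RefSeq-style accessions (NM/NR/NP/XM/XR/XP), keep per query only
the hits tied at the minimum E-value, attach Entrez/symbol/biotype annotation
and drop unannotated hits, then collapse duplicated gene symbols within a
query to the lowest-E occurrence.  The catalog aggregates per-query gene
lists into a unique Entrez set with a biotype tally.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .exceptions import ParseError

logger = logging.getLogger(__name__)

#: Accession prefixes retained (mRNA, non-coding RNA, and protein RefSeq classes).
ALLOWED_PREFIXES = frozenset({"NM", "NR", "NP", "XM", "XR", "XP"})

BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

BIOTYPES = ("protein coding", "lncRNA", "pseudogene", "TEC")


class BlastHit(NamedTuple):
    query_id: str
    accession: str
    identity: float
    e_value: float
    bitscore: float


@dataclass(frozen=True)
class AnnotatedHit:
    query_id: str
    accession: str
    e_value: float
    entrez_id: int
    symbol: str
    biotype: str


@dataclass
class TargetCatalog:
    """Per-query best genes plus the unique-gene set and biotype tally."""

    per_query: dict[str, list[tuple[int, str, float]]]
    unique_genes: set[int]
    biotype_tally: Counter = field(default_factory=Counter)

    def __post_init__(self):
        assert sum(self.biotype_tally.values()) == len(self.unique_genes)


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix (annotation tables are versionless)."""
    head, sep, tail = accession.rpartition(".")
    if sep and tail.isdigit():
        return head
    return accession


def accession_prefix(accession: str) -> str:
    return accession.split("_", 1)[0]


def parse_blast_tabular(path) -> list[BlastHit]:
    """Parse a 12-column tab-separated BLAST hit table (outfmt-6 column order).

    Malformed lines raise :class:`ParseError` naming the line number.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        accession=fields[1],
                        identity=float(fields[2]),
                        e_value=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def filter_accession_prefix(hits: Iterable[BlastHit]) -> list[BlastHit]:
    """Keep hits whose accession prefix (text before '_') is an allowed RefSeq class."""
    hits = list(hits)
    kept = [h for h in hits if accession_prefix(h.accession) in ALLOWED_PREFIXES]
    dropped = len(hits) - len(kept)
    if dropped:
        logger.info("prefix filter dropped %d of %d hits", dropped, len(hits))
    return kept


def best_hits_per_query(hits: Iterable[BlastHit]) -> list[BlastHit]:
    """Per query, keep every hit tied at the minimum E-value (ties retained)."""
    best: dict[str, float] = {}
    hits = list(hits)
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.e_value < cur:
            best[h.query_id] = h.e_value
    return [h for h in hits if h.e_value == best[h.query_id]]


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read an annotation table (accession, entrez_id, symbol, biotype).

    ``entrez_id`` may be empty (no Entrez assignment); such rows are kept here
    and pruned by :func:`annotate_and_prune`.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"accession": str, "symbol": str, "biotype": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = {"accession", "entrez_id", "symbol", "biotype"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: annotation table missing columns {sorted(missing)}")
    return df


def annotate_and_prune(
    hits: Iterable[BlastHit], annotation: pd.DataFrame
) -> list[AnnotatedHit]:
    """Attach Entrez/symbol/biotype; drop hits without an Entrez-bearing row.

    The accession version suffix is stripped before lookup.
    """
    ann = annotation.set_index(annotation["accession"].map(strip_version))
    out: list[AnnotatedHit] = []
    removed = 0
    for h in hits:
        key = strip_version(h.accession)
        if key not in ann.index:
            removed += 1
            continue
        row = ann.loc[key]
        if pd.isna(row["entrez_id"]):
            removed += 1
            continue
        out.append(
            AnnotatedHit(
                query_id=h.query_id,
                accession=h.accession,
                e_value=h.e_value,
                entrez_id=int(row["entrez_id"]),
                symbol=str(row["symbol"]),
                biotype=str(row["biotype"]),
            )
        )
    if removed:
        logger.info("annotation pruning removed %d hits", removed)
    return out


def dedupe_symbols(annotated: Iterable[AnnotatedHit]) -> dict[str, list[AnnotatedHit]]:
    """Within each query, keep one hit per gene symbol, at its minimum E-value.

    Symbol comparison is case-insensitive (symbol case is inconsistent across
    sources).  Idempotent.  Returns query_id -> hits sorted by (E-value, symbol).
    """
    best: dict[tuple[str, str], AnnotatedHit] = {}
    for h in annotated:
        key = (h.query_id, h.symbol.upper())
        cur = best.get(key)
        if cur is None or h.e_value < cur.e_value:
            best[key] = h
    per_query: dict[str, list[AnnotatedHit]] = {}
    for h in best.values():
        per_query.setdefault(h.query_id, []).append(h)
    for q in per_query:
        per_query[q].sort(key=lambda h: (h.e_value, h.symbol.upper()))
    return per_query


def build_catalog(per_query: dict[str, list[AnnotatedHit]]) -> TargetCatalog:
    """Aggregate per-query gene lists into a catalog.

    ``unique_genes`` is the union of Entrez ids over queries; the biotype tally
    counts each unique gene once regardless of how many queries hit it.
    """
    pq = {
        q: [(h.entrez_id, h.symbol, h.e_value) for h in hits]
        for q, hits in sorted(per_query.items())
    }
    gene_biotype: dict[int, str] = {}
    for hits in per_query.values():
        for h in hits:
            gene_biotype[h.entrez_id] = h.biotype
    tally = Counter(gene_biotype.values())
    return TargetCatalog(
        per_query=pq, unique_genes=set(gene_biotype), biotype_tally=tally
    )


def reduce_hits(hits: Iterable[BlastHit], annotation: pd.DataFrame) -> TargetCatalog:
    """Full reduction chain: prefix filter -> best hits -> annotate -> dedupe -> catalog."""
    return build_catalog(
        dedupe_symbols(
            annotate_and_prune(
                best_hits_per_query(filter_accession_prefix(hits)), annotation
            )
        )
    )


def cross_annotate(
    catalog: TargetCatalog, term_genes: set[int], term_id: str = ""
) -> tuple[set[int], int]:
    """Intersect the catalog's unique genes with an external gene set.

    Returns (member subset, count); e.g. used to ask how many catalog genes
    already carry a given GO annotation.
    """
    members = catalog.unique_genes & set(term_genes)
    return members, len(members)


def write_catalog_tsv(per_query: dict[str, list[AnnotatedHit]], path) -> None:
    """Write the deduplicated per-query gene list as a TSV."""
    rows = [
        {
            "query_id": q,
            "entrez_id": h.entrez_id,
            "symbol": h.symbol,
            "biotype": h.biotype,
            "best_evalue": h.e_value,
        }
        for q in sorted(per_query)
        for h in per_query[q]
    ]
    pd.DataFrame(
        rows, columns=["query_id", "entrez_id", "symbol", "biotype", "best_evalue"]
    ).to_csv(path, sep="\t", index=False)


def write_tally_json(catalog: TargetCatalog, path) -> None:
    payload = {
        "n_unique_genes": len(catalog.unique_genes),
        "biotype_tally": dict(sorted(catalog.biotype_tally.items())),
        "n_queries": len(catalog.per_query),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
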