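"""Over-representation analysis and kappa-score clustering of enriched terms.

A query gene list is tested against each set in a collection with the
hypergeometric upper tail (one-sided Fisher) over a background universe, and
p-values are Benjamini-Hochberg adjusted within the collection; a term is
significant below adjusted p 0.05.  Significant terms are then grouped by
chance-corrected agreement (Cohen's kappa) of their gene memberships: each
term seeds a candidate group of all terms with kappa at or above a threshold
(default 0.5), groups sharing more than half their terms merge iteratively,
and each final group is labelled by its leading term — the member with the
smallest adjusted p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidParameterError, ParseError, UndefinedKappaError

ALPHA = 0.05
KAPPA_THRESHOLD = 0.5


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset
    source: str = ""

    def __post_init__(self):
        if not self.genes:
            raise InvalidParameterError(f"gene set {self.set_id!r} is empty")


@dataclass
class TermCluster:
    group_id: int
    member_terms: list[str]
    leading_term: str
    kappa: dict[tuple[str, str], float] = field(default_factory=dict)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated id, description, genes."""
    sets: list[GeneSet] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs id, description and >=1 gene"
                )
            set_id, name, *genes = fields
            if set_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            sets.append(GeneSet(set_id=set_id, name=name, genes=frozenset(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes when drawing *n* items without replacement from a
    universe of *N* containing *K* successes.  Decreasing in k; P(X >= 0) = 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise InvalidParameterError(f"need 0 <= K, n <= N, got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise InvalidParameterError(
            f"k={k} impossible for K={K}, n={n} (must satisfy 0 <= k <= min(K, n))"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query,
    collection: list[GeneSet],
    universe=None,
    alpha: float = ALPHA,
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *query* across a collection.

    The universe defaults to the union of all collection genes (all available
    annotations); the query is intersected with the universe before testing.
    One row per set; BH adjustment spans every tested set in the collection.
    No size filters apply by default.

    Returns a DataFrame (set_id, name, source, k, K, n, N, p_value, adj_p,
    significant) sorted by adjusted then raw p.
    """
    if universe is None:
        universe = set().union(*(s.genes for s in collection)) if collection else set()
    else:
        universe = set(universe)
    query = set(query) & universe
    tested = [
        s
        for s in collection
        if len(s.genes & universe) >= min_set_size
        and (max_set_size is None or len(s.genes & universe) <= max_set_size)
    ]
    rows = []
    N, n = len(universe), len(query)
    for s in tested:
        genes = s.genes & universe
        K = len(genes)
        k = len(genes & query)
        rows.append(
            {
                "set_id": s.set_id,
                "name": s.name,
                "source": s.source,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeometric_p(k, K, n, N) if N else 1.0,
            }
        )
    df = pd.DataFrame(
        rows, columns=["set_id", "name", "source", "k", "K", "n", "N", "p_value"]
    )
    df["adj_p"] = bh_adjust(df["p_value"]) if len(df) else []
    df["significant"] = df["adj_p"] < alpha
    return df.sort_values(["adj_p", "p_value", "set_id"], ignore_index=True)


def kappa_score(genes_a, genes_b, reference) -> float:
    """Cohen's kappa between two sets' membership indicators over *reference*.

    kappa = (p_o - p_e) / (1 - p_e) from the 2x2 contingency of joint
    membership.  1 for identical sets; bounded above by 1; symmetric.  Raises
    :class:`UndefinedKappaError` when chance agreement p_e = 1 (both sets
    empty, or both equal to the whole reference).
    """
    reference = set(reference)
    genes_a, genes_b = set(genes_a), set(genes_b)
    if not (genes_a | genes_b) <= reference:
        raise InvalidParameterError("reference must contain both gene sets")
    N = len(reference)
    if N < 2:
        raise InvalidParameterError("reference must contain at least 2 genes")
    a = len(genes_a & genes_b)
    b = len(genes_a - genes_b)
    c = len(genes_b - genes_a)
    d = N - a - b - c
    p_o = (a + d) / N
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if p_e == 1.0:
        raise UndefinedKappaError(
            "chance agreement is 1 (sets both empty or both the full reference)"
        )
    return (p_o - p_e) / (1.0 - p_e)


def cluster_terms(
    results: pd.DataFrame,
    collection: list[GeneSet],
    kappa_threshold: float = KAPPA_THRESHOLD,
) -> list[TermCluster]:
    """Group significant terms by kappa-score similarity of their gene sets.

    The membership universe for kappa is the union of genes of all significant
    terms.  Each significant term seeds a candidate group containing itself
    plus all terms with kappa >= *kappa_threshold* to it; groups sharing more
    than 50% of the smaller group's terms merge until a fixed point.  The
    leading term is the member with the minimum adjusted p (ties broken by
    smaller set_id).  Deterministic and independent of input order.
    """
    sig = results[results["significant"]].copy()
    if len(sig) == 0:
        return []
    by_id = {s.set_id: s for s in collection}
    term_ids = sorted(sig["set_id"])
    missing = [t for t in term_ids if t not in by_id]
    if missing:
        raise InvalidParameterError(f"terms absent from collection: {missing}")
    adj_p = dict(zip(sig["set_id"], sig["adj_p"]))
    reference = set().union(*(by_id[t].genes for t in term_ids))

    kappa: dict[tuple[str, str], float] = {}
    for i, t1 in enumerate(term_ids):
        for t2 in term_ids[i + 1 :]:
            g1, g2 = by_id[t1].genes, by_id[t2].genes
            # identical memberships are perfect agreement even when the 2x2
            # table degenerates (both sets spanning the whole reference)
            kappa[(t1, t2)] = (
                1.0 if g1 == g2 else kappa_score(g1, g2, reference)
            )

    def pair_kappa(t1: str, t2: str) -> float:
        return kappa[(t1, t2)] if (t1, t2) in kappa else kappa[(t2, t1)]

    groups: list[frozenset] = []
    for t in term_ids:
        members = {t} | {
            o for o in term_ids if o != t and pair_kappa(t, o) >= kappa_threshold
        }
        groups.append(frozenset(members))
    groups = sorted(set(groups), key=lambda g: sorted(g))

    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                g1, g2 = groups[i], groups[j]
                shared = len(g1 & g2)
                if shared > 0.5 * min(len(g1), len(g2)):
                    groups[i] = g1 | g2
                    del groups[j]
                    groups = sorted(set(groups), key=lambda g: sorted(g))
                    merged = True
                    break
            if merged:
                break

    clusters = []
    for gid, members in enumerate(groups, start=1):
        ordered = sorted(members)
        leader = min(ordered, key=lambda t: (adj_p[t], t))
        pair_k = {
            (a, b): pair_kappa(a, b)
            for i, a in enumerate(ordered)
            for b in ordered[i + 1 :]
        }
        clusters.append(
            TermCluster(
                group_id=gid, member_terms=ordered, leading_term=leader, kappa=pair_k
            )
        )
    return clusters


def write_enrichment_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_clusters_json(clusters: list[TermCluster], path) -> None:
    payload = [
        {
            "group_id": c.group_id,
            "members": c.member_terms,
            "leading_term": c.leading_term,
            "kappa": {f"{a}|{b}": round(v, 6) for (a, b), v in sorted(c.kappa.items())},
        }
        for c in clusters
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
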