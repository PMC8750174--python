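"""Shell-expanded protein-protein interaction networks and LCC analysis.

Starting from a seed list of target genes, the network grows by confidence
shells over a scored interactome (STRING-style combined scores, integers in
[41, 998]): the 1st shell holds direct interactors of the targets at or above
a score threshold, the 2nd shell holds interactors of the 1st shell.  The
final edge set is the induced subgraph over the selected nodes at the
applicable threshold.  Summaries report totals, target/flag fractions, and
the largest connected component (LCC), counting only nodes with at least one
interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .exceptions import InvalidParameterError, ParseError

SCORE_MIN, SCORE_MAX = 41, 998

#: Score regarded as very high confidence for an interaction.
VERY_HIGH_CONFIDENCE = 900
#: Score regarded as high confidence.
HIGH_CONFIDENCE = 700

ROLES = ("target", "shell1", "shell2")


@dataclass
class PPINetwork:
    """A role-tagged interaction network.

    ``graph`` is an undirected networkx graph whose nodes carry a ``role``
    attribute in {target, shell1, shell2} and whose edges carry ``score``.
    """

    graph: nx.Graph
    shells: int
    t1: int
    t2: int

    @property
    def roles(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="role"))

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, r in self.graph.nodes(data="role") if r == role}


@dataclass(frozen=True)
class NetworkSummary:
    total_genes: int
    n_targets: int
    pct_targets: float
    n_interactions: int
    n_flagged: int
    pct_flagged: float
    lcc_size: int
    pct_lcc: float

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "n_targets": self.n_targets,
            "pct_targets": self.pct_targets,
            "n_interactions": self.n_interactions,
            "n_flagged": self.n_flagged,
            "pct_flagged": self.pct_flagged,
            "lcc_size": self.lcc_size,
            "pct_lcc": self.pct_lcc,
        }


def load_interactions(path, min_score: int = SCORE_MIN) -> pd.DataFrame:
    """Load a scored interaction TSV (protein1, protein2, combined_score).

    Scores outside [41, 998] are a format error.  Edges below *min_score* are
    excluded; duplicate unordered pairs collapse to their maximum score.
    Returns a DataFrame (node_a, node_b, score) with node_a < node_b.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})
    missing = {"protein1", "protein2", "combined_score"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: interaction table missing columns {sorted(missing)}")
    if len(df) == 0:
        return pd.DataFrame(columns=["node_a", "node_b", "score"])
    scores = df["combined_score"].astype(int)
    bad = df[(scores < SCORE_MIN) | (scores > SCORE_MAX)]
    if len(bad):
        raise ParseError(
            f"{path}: {len(bad)} interaction scores outside [{SCORE_MIN}, {SCORE_MAX}]"
        )
    if (df["protein1"] == df["protein2"]).any():
        raise ParseError(f"{path}: self-interactions are not allowed")
    a = df[["protein1", "protein2"]].min(axis=1)
    b = df[["protein1", "protein2"]].max(axis=1)
    out = pd.DataFrame({"node_a": a, "node_b": b, "score": scores})
    out = (
        out.groupby(["node_a", "node_b"], as_index=False)["score"]
        .max()
        .sort_values(["node_a", "node_b"], ignore_index=True)
    )
    return out[out["score"] >= min_score].reset_index(drop=True)


def _check_threshold(name: str, value: int) -> None:
    if not (SCORE_MIN <= value <= SCORE_MAX):
        raise InvalidParameterError(
            f"{name} must lie in [{SCORE_MIN}, {SCORE_MAX}], got {value}"
        )


def expand_network(
    targets: set,
    edges: pd.DataFrame,
    shells: int = 1,
    t1: int = VERY_HIGH_CONFIDENCE,
    t2: int = VERY_HIGH_CONFIDENCE,
) -> PPINetwork:
    """Grow a role-tagged network from *targets* by confidence shells.

    shells=0: targets only, edges among targets at score >= t1.
    shells=1: plus direct interactors of targets at >= t1.
    shells=2: plus interactors of the 1st shell at >= t2 (nodes not already
    target/shell1).  The edge set is the induced subgraph over selected nodes:
    edges among target/shell1 nodes need score >= t1, edges touching a shell2
    node need score >= t2.

    An empty target set yields an empty network, not an error.
    """
    if shells not in (0, 1, 2):
        raise InvalidParameterError(f"shells must be 0, 1, or 2, got {shells}")
    _check_threshold("t1", t1)
    _check_threshold("t2", t2)
    targets = set(targets)

    full = nx.Graph()
    for row in edges.itertuples(index=False):
        full.add_edge(row.node_a, row.node_b, score=int(row.score))

    def neighbors_at(nodes: set, threshold: int) -> set:
        found = set()
        for n in nodes & set(full.nodes):
            for m in full.neighbors(n):
                if full.edges[n, m]["score"] >= threshold:
                    found.add(m)
        return found

    shell1: set = set()
    shell2: set = set()
    if shells >= 1:
        shell1 = neighbors_at(targets, t1) - targets
    if shells == 2:
        shell2 = neighbors_at(shell1, t2) - targets - shell1

    g = nx.Graph()
    for n in targets:
        g.add_node(n, role="target")
    for n in shell1:
        g.add_node(n, role="shell1")
    for n in shell2:
        g.add_node(n, role="shell2")

    inner = targets | shell1
    for u, v, score in full.edges(data="score"):
        if u not in g or v not in g:
            continue
        threshold = t1 if (u in inner and v in inner) else t2
        if score >= threshold:
            g.add_edge(u, v, score=score)
    return PPINetwork(graph=g, shells=shells, t1=t1, t2=t2)


def largest_connected_component(network: PPINetwork | nx.Graph) -> set:
    """Return the node set of the largest connected component.

    Only nodes with at least one edge are considered (isolated nodes form
    trivial components of size 1 and are ignored unless nothing else exists).
    Ties break on the lexicographically smallest sorted node list, so the
    result is deterministic.  An empty network yields the empty set.
    """
    g = network.graph if isinstance(network, PPINetwork) else network
    g = g.subgraph([n for n, d in g.degree() if d > 0])
    comps = [set(c) for c in nx.connected_components(g)]
    if not comps:
        return set()
    return max(comps, key=lambda c: (len(c), sorted(c, reverse=True)))


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def summarize_network(
    network: PPINetwork, targets: set, flag_set: set = frozenset()
) -> NetworkSummary:
    """Summary counts with one-decimal percents relative to non-isolated genes.

    ``total_genes`` counts nodes with at least one interaction; targets,
    flagged genes (e.g. genes carrying an oxidative-stress annotation) and the
    LCC are reported as counts plus percent of total_genes.
    """
    g = network.graph
    connected = {n for n, d in g.degree() if d > 0}
    total = len(connected)
    n_targets = len(connected & set(targets))
    n_flagged = len(connected & set(flag_set))
    lcc = largest_connected_component(network)
    return NetworkSummary(
        total_genes=total,
        n_targets=n_targets,
        pct_targets=_pct(n_targets, total),
        n_interactions=g.number_of_edges(),
        n_flagged=n_flagged,
        pct_flagged=_pct(n_flagged, total),
        lcc_size=len(lcc),
        pct_lcc=_pct(len(lcc), total),
    )


def write_network(network: PPINetwork, edges_path, roles_path) -> None:
    """Write the edge list and node-role sidecar as TSVs."""
    rows = [
        {"node_a": min(u, v), "node_b": max(u, v), "score": s}
        for u, v, s in network.graph.edges(data="score")
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "score"]).sort_values(
        ["node_a", "node_b"]
    ).to_csv(edges_path, sep="\t", index=False)
    roles = [
        {"node": n, "role": r} for n, r in sorted(network.graph.nodes(data="role"))
    ]
    pd.DataFrame(roles, columns=["node", "role"]).to_csv(
        roles_path, sep="\t", index=False
    )


def write_summary_json(summaries: dict[str, NetworkSummary], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: s.to_dict() for k, s in summaries.items()}, fh, indent=2)
        fh.write("\n")
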