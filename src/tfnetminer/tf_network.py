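"""Assembly and annotation of the TF interaction network.

Edges are the literature-retained gene pairs whose GO annotation distance is
strictly below 1.0; where structural evidence exists, the structural call and
mean interaction score are attached, but GO-validated edges without structure
are retained (structure coverage is always partial). Topology annotation adds
degree, the clustering coefficient C_i = 2n / (k_i (k_i − 1)), and betweenness
centrality, both raw and normalized per connected component by
(n_c − 1)(n_c − 2)/2 so it is commensurable with the [0, 1] features used in
node scoring. Evidence tiers classify nodes by membership in a
disease-specific list (HIGH), a cancer/signalling list (MEDIUM), or any other
pathway list (LOW); edges inherit the higher endpoint tier except that LOW
requires both endpoints LOW.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .annotation_similarity import EdgeGoSimilarity, TFFlag, is_go_interacting
from .errors import DataError
from .structure_interaction import PairInteractionCall

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "compute_topology",
    "tier_evidence",
    "edge_tier",
    "node_table",
    "edge_table",
    "TIER_ORDER",
]

TIER_ORDER = ("HIGH", "MEDIUM", "LOW", "UNKNOWN")


def build_network(
    retained_pairs: Iterable[tuple[str, str]],
    go_results: Mapping[tuple[str, str], EdgeGoSimilarity],
    structure_calls: Mapping[tuple[str, str], PairInteractionCall] | None = None,
    tf_flags: Mapping[str, TFFlag] | None = None,
    relations: Mapping[tuple[str, str], str | None] | None = None,
    association_scores: Mapping[tuple[str, str], float] | None = None,
) -> nx.Graph:
    """Build the undirected TF interaction network.

    Every retained pair must have a GO comparison; pairs with distance < 1.0
    become edges. Structural calls and relation labels are attached where
    available. Node attribute ``is_tf`` comes from ``tf_flags`` (default
    False). Self-loops are rejected.
    """
    structure_calls = structure_calls or {}
    tf_flags = tf_flags or {}
    relations = relations or {}
    association_scores = association_scores or {}
    retained = [tuple(sorted(p)) for p in retained_pairs]
    missing = [p for p in retained if p not in go_results]
    if missing:
        raise DataError(
            f"{len(missing)} retained pairs lack GO comparisons: {sorted(missing)[:10]}"
        )
    g = nx.Graph()
    for pair in retained:
        a, b = pair
        if a == b:
            raise DataError(f"self-pair {a!r} cannot form an edge")
        sim = go_results[pair]
        if not is_go_interacting(sim):
            continue
        call = structure_calls.get(pair)
        g.add_edge(
            a,
            b,
            go_distance=sim.distance_overall,
            go_similarity=sim.similarity,
            structural_score=(
                call.mean_interaction_score if call is not None else None
            ),
            structural_interacting=(call.is_interacting if call is not None else None),
            relation=relations.get(pair),
            association_score=association_scores.get(pair),
        )
    for node in g.nodes:
        flag = tf_flags.get(node)
        g.nodes[node]["is_tf"] = bool(flag.is_tf) if flag is not None else False
    n_tf_edges = sum(
        1 for a, b in g.edges if g.nodes[a]["is_tf"] or g.nodes[b]["is_tf"]
    )
    logger.info(
        "network: %d nodes, %d edges (%d touching a TF)",
        g.number_of_nodes(), g.number_of_edges(), n_tf_edges,
    )
    return g


def compute_topology(g: nx.Graph) -> nx.Graph:
    """Annotate every node with degree, clustering coefficient, and raw +
    per-component normalized betweenness. Isolated nodes get zeros."""
    degree = dict(g.degree())
    clustering = nx.clustering(g)
    betweenness_raw = nx.betweenness_centrality(g, normalized=False)
    for comp in nx.connected_components(g):
        nc = len(comp)
        denom = (nc - 1) * (nc - 2) / 2.0
        for node in comp:
            g.nodes[node]["degree"] = degree[node]
            g.nodes[node]["clustering"] = float(clustering[node])
            g.nodes[node]["betweenness_raw"] = float(betweenness_raw[node])
            g.nodes[node]["betweenness_norm"] = (
                float(betweenness_raw[node]) / denom if denom > 0 else 0.0
            )
    return g


def edge_tier(tier_a: str, tier_b: str) -> str:
    """Edge tier from endpoint tiers: HIGH dominates, then MEDIUM; LOW only
    when both endpoints are LOW. UNKNOWN endpoints count as LOW."""
    eff = {"UNKNOWN": "LOW"}
    a, b = eff.get(tier_a, tier_a), eff.get(tier_b, tier_b)
    for t in (a, b):
        if t not in ("HIGH", "MEDIUM", "LOW"):
            raise DataError(f"unknown tier {t!r}")
    if "HIGH" in (a, b):
        return "HIGH"
    if "MEDIUM" in (a, b):
        return "MEDIUM"
    return "LOW"


def tier_evidence(
    g: nx.Graph,
    colon_list: Iterable[str],
    cancer_list: Iterable[str],
    other_list: Iterable[str],
) -> nx.Graph:
    """Assign node and edge evidence tiers from pathway-membership lists.

    Node rule: disease-specific list → HIGH; cancer/signalling list → MEDIUM;
    any other pathway list → LOW; none → UNKNOWN (flagged, treated as LOW in
    the edge rule).
    """
    colon, cancer, other = set(colon_list), set(cancer_list), set(other_list)
    for node in g.nodes:
        if node in colon:
            tier = "HIGH"
        elif node in cancer:
            tier = "MEDIUM"
        elif node in other:
            tier = "LOW"
        else:
            tier = "UNKNOWN"
        g.nodes[node]["tier"] = tier
    for a, b in g.edges:
        ta, tb = g.nodes[a]["tier"], g.nodes[b]["tier"]
        g.edges[a, b]["tier"] = edge_tier(ta, tb)
        g.edges[a, b]["tier_flagged"] = "UNKNOWN" in (ta, tb)
    return g


def read_id_list(path: str | Path) -> list[str]:
    """Membership list: one id per line, '#' comments allowed."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def node_table(g: nx.Graph) -> pd.DataFrame:
    cols = [
        "node", "is_tf", "degree", "clustering",
        "betweenness_raw", "betweenness_norm", "tier",
    ]
    rows = [
        {
            "node": n,
            "is_tf": d.get("is_tf", False),
            "degree": d.get("degree"),
            "clustering": d.get("clustering"),
            "betweenness_raw": d.get("betweenness_raw"),
            "betweenness_norm": d.get("betweenness_norm"),
            "tier": d.get("tier", ""),
        }
        for n, d in sorted(g.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=cols)


def edge_table(g: nx.Graph) -> pd.DataFrame:
    cols = [
        "protein_a", "protein_b", "association_score", "go_distance",
        "go_similarity", "structural_score", "structural_interacting",
        "relation", "tier",
    ]
    rows = []
    for a, b in sorted(tuple(sorted(e)) for e in g.edges):
        d = g.edges[a, b]
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "association_score": d.get("association_score"),
                "go_distance": d.get("go_distance"),
                "go_similarity": d.get("go_similarity"),
                "structural_score": d.get("structural_score"),
                "structural_interacting": d.get("structural_interacting"),
                "relation": d.get("relation") or "",
                "tier": d.get("tier", ""),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export; None attributes are dropped (GraphML has no null)."""
    h = g.copy()
    for _, d in h.nodes(data=True):
        for k in [k for k, v in d.items() if v is None]:
            del d[k]
    for _, _, d in h.edges(data=True):
        for k in [k for k, v in d.items() if v is None]:
            del d[k]
    nx.write_graphml(h, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path), node_type=str)
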