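"""Node prioritization: biological node scores, combined node strength, and
hypergeometric node–node associations.

Each node carries four features: clustering coefficient, normalized
betweenness, a GO annotation similarity score (mean GO similarity of its
incident edges), and a protein interaction propensity score (mean structural
score of its incident edges divided by the network-wide mean edge structural
score — proteins tend to interact within their own structural families, so a
node whose edges score above the network average is structurally favored).
Node strength combines the features either un-weighted (arithmetic mean) or
weighted, with the structural propensity emphasized at weight 0.4 against
0.2 for each remaining feature; a literal variant that additionally counts
propensity inside the 0.2 bracket is provided for comparison.

Node–node association: two nodes with neighbor counts n1 and n2 among N
network proteins sharing m neighbors are scored by the hypergeometric point
probability of that overlap; small p-values mark unexpectedly shared
interaction partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .hypergeom import pair_association_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "PrioritizationConfig",
    "node_go_score",
    "node_propensity_score",
    "node_strength_unweighted",
    "node_strength_weighted",
    "hypergeometric_association",
    "compute_node_features",
    "rank_nodes",
]

FEATURES = ("clustering", "betweenness_norm", "go_score", "propensity")
SCHEMES = ("unweighted", "weighted", "weighted_literal")


@dataclass(frozen=True)
class PrioritizationConfig:
    """Scoring scheme and weights (defaults are the empirical constants)."""

    scheme: str = "weighted"
    w_propensity: float = 0.4
    w_other: float = 0.2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")


def node_go_score(g: nx.Graph, node) -> float:
    """Mean GO similarity (1 − distance) over the node's incident edges;
    0 for an isolated node (flagged in the log)."""
    edges = list(g.edges(node, data=True))
    if not edges:
        logger.info("node %s is isolated; GO score set to 0", node)
        return 0.0
    return sum(d["go_similarity"] for _, _, d in edges) / len(edges)


def _mean_structural(edge_data, count: int) -> float:
    """Mean structural score over ``count`` edges, missing scores as 0."""
    if count == 0:
        return 0.0
    return sum((d.get("structural_score") or 0.0) for d in edge_data) / count


def node_propensity_score(g: nx.Graph, node) -> float:
    """Node mean structural edge score over the network mean.

    Edges without structural data contribute 0 to the means but stay in the
    counts, provided at least one edge network-wide is structurally scored;
    a fully unscored network yields propensity 0 everywhere (flagged).
    """
    all_edges = [d for _, _, d in g.edges(data=True)]
    if not any(d.get("structural_score") is not None for d in all_edges):
        logger.warning("no structurally scored edges; propensity is 0 network-wide")
        return 0.0
    network_mean = _mean_structural(all_edges, len(all_edges))
    if network_mean == 0.0:
        return 0.0
    incident = [d for _, _, d in g.edges(node, data=True)]
    if not incident:
        logger.info("node %s is isolated; propensity set to 0", node)
        return 0.0
    return _mean_structural(incident, len(incident)) / network_mean


def _check_features(features) -> None:
    missing = [f for f in FEATURES if f not in features or features[f] is None]
    if missing:
        raise DataError(f"missing node features: {missing}")


def node_strength_unweighted(features) -> float:
    """Arithmetic mean of the four node features."""
    _check_features(features)
    return sum(float(features[f]) for f in FEATURES) / 4.0


def node_strength_weighted(features, config: PrioritizationConfig | None = None) -> float:
    """Weighted node strength.

    Default scheme: 0.4·propensity + 0.2·(clustering + betweenness + GO
    score), weights summing to 1.0 while keeping the 2:1 structural emphasis.
    The ``weighted_literal`` scheme also adds propensity inside the 0.2
    bracket (weights summing to 1.2), exactly as the weighted formula is
    printed in its source description.
    """
    _check_features(features)
    config = config or PrioritizationConfig()
    wp, wo = config.w_propensity, config.w_other
    others = (
        float(features["clustering"])
        + float(features["betweenness_norm"])
        + float(features["go_score"])
    )
    if config.scheme in ("weighted", "unweighted"):
        return wp * float(features["propensity"]) + wo * others
    if config.scheme == "weighted_literal":
        return wp * float(features["propensity"]) + wo * (
            others + float(features["propensity"])
        )
    raise ConfigError(f"unknown scheme {config.scheme!r}")


def hypergeometric_association(n1: int, n2: int, m: int, total: int) -> float:
    """Point probability of sharing exactly ``m`` neighbors (see module
    docstring); computed in log-factorial space."""
    return pair_association_pvalue(n1, n2, m, total)


def compute_node_features(g: nx.Graph) -> nx.Graph:
    """Attach go_score and propensity to every node (topology must exist)."""
    for node in g.nodes:
        if "clustering" not in g.nodes[node]:
            raise DataError("topology not computed; run compute_topology first")
        g.nodes[node]["go_score"] = node_go_score(g, node)
        g.nodes[node]["propensity"] = node_propensity_score(g, node)
    return g


def _strength(g: nx.Graph, node, config: PrioritizationConfig) -> float:
    feats = {f: g.nodes[node].get(f) for f in FEATURES}
    if config.scheme == "unweighted":
        return node_strength_unweighted(feats)
    return node_strength_weighted(feats, config)


def rank_nodes(
    g: nx.Graph, config: PrioritizationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank all nodes by node strength and score TF-pair associations.

    Returns ``(ranking, associations)``. The ranking is sorted by strength
    descending, ties broken by node id. The association table covers TF pairs
    within a connected component, with the hypergeometric p-value of their
    shared-neighbor count, a BH q-value column, and a significance flag at
    the configured α (no multiple-testing correction is applied to the flag).
    """
    config = config or PrioritizationConfig()
    rows = []
    for node in g.nodes:
        feats = {f: float(g.nodes[node].get(f)) for f in FEATURES}
        rows.append(
            {
                "node": node,
                "is_tf": bool(g.nodes[node].get("is_tf", False)),
                "node_strength": _strength(g, node, config),
                **feats,
                "degree": g.nodes[node].get("degree", 0),
                "tier": g.nodes[node].get("tier", ""),
            }
        )
    ranking = pd.DataFrame(rows).sort_values(
        ["node_strength", "node"], ascending=[False, True], kind="mergesort"
    )
    ranking["rank"] = range(1, len(ranking) + 1)
    ranking = ranking.reset_index(drop=True)

    total = g.number_of_nodes()
    tfs = sorted(n for n in g.nodes if g.nodes[n].get("is_tf"))
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            comp_of[n] = ci
    assoc_rows = []
    for a, b in combinations(tfs, 2):
        if comp_of[a] != comp_of[b]:
            continue
        na, nb = set(g[a]), set(g[b])
        m = len(na & nb)
        p = hypergeometric_association(len(na), len(nb), m, total)
        assoc_rows.append(
            {
                "protein_a": a, "protein_b": b,
                "n1": len(na), "n2": len(nb), "m": m, "N": total,
                "p_value": p,
            }
        )
    assoc = pd.DataFrame(
        assoc_rows, columns=["protein_a", "protein_b", "n1", "n2", "m", "N", "p_value"]
    )
    if len(assoc):
        assoc["q_value"] = multipletests(assoc["p_value"], method="fdr_bh")[1]
        assoc["significant"] = assoc["p_value"] < config.alpha
        assoc = assoc.sort_values(
            ["p_value", "protein_a", "protein_b"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        assoc["q_value"] = []
        assoc["significant"] = []
    return ranking, assoc
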