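"""TF-anchored functional modules: enumeration, scoring, and significance.

A module is a connected induced subgraph of the network that contains at
least one TF, built from a prioritized TF and its direct interactors (the
TF's ego network). Modules of size 3 up to a configurable cap are enumerated
exhaustively within each ego network, deduplicated across anchors, and
scored by the mean node strength of their members. Per-TF significance is a
hypergeometric upper tail 1 − Σ_{i<k} pmf(i); because the symbols of the
printed formula admit several parameter bindings, the binding is an explicit,
recorded choice (see ``module_significance``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigError, DataError
from .hypergeom import hypergeom_complement_cdf

logger = logging.getLogger(__name__)

__all__ = [
    "Module",
    "ModuleSignificance",
    "enumerate_connected_subgraphs",
    "extract_modules",
    "score_module",
    "module_tf_pvalue",
    "module_significance",
    "rank_modules",
]

BINDINGS = ("literal", "modules", "tf-content")


@dataclass(frozen=True)
class Module:
    module_id: str
    anchor_tf: str
    nodes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class ModuleSignificance:
    anchor_tf: str
    module_id: str
    p_value: float
    binding: str
    population: int
    successes: int
    draws: int
    k: int


def enumerate_connected_subgraphs(
    g: nx.Graph, root, min_size: int = 3, max_size: int = 8, guard: int = 100_000
) -> list[frozenset]:
    """All connected induced subgraphs of ``g`` containing ``root`` with
    ``min_size`` ≤ size ≤ ``max_size``.

    Breadth-first growth with node-set deduplication; ``guard`` caps the
    number of distinct subgraphs visited per root (truncation is logged).
    """
    start = frozenset([root])
    seen = {start}
    frontier = [start]
    out: list[frozenset] = []
    truncated = False
    while frontier:
        sub = frontier.pop()
        if min_size <= len(sub) <= max_size:
            out.append(sub)
        if len(sub) >= max_size:
            continue
        neighborhood = set().union(*(set(g[v]) for v in sub)) - sub
        for v in sorted(neighborhood):
            grown = sub | {v}
            if grown in seen:
                continue
            if len(seen) >= guard:
                truncated = True
                break
            seen.add(grown)
            frontier.append(grown)
        if truncated:
            break
    if truncated:
        logger.warning(
            "subgraph enumeration for root %s truncated at guard=%d", root, guard
        )
    return out


def extract_modules(
    g: nx.Graph,
    ranking: pd.DataFrame,
    size_cap: int = 8,
    tf_fraction: float = 0.5,
    guard: int = 100_000,
) -> list[Module]:
    """Enumerate modules anchored on prioritized TFs.

    Prioritized TFs are the top ``tf_fraction`` of TFs by rank. For each, all
    connected induced subgraphs of its ego network (the TF plus its direct
    interactors) containing the TF, with 3 ≤ size ≤ ``size_cap``, are
    emitted. Identical node sets arising from different anchors are kept
    once, anchored to the higher-ranked TF.
    """
    if size_cap < 3:
        raise ConfigError(f"size_cap must be ≥ 3, got {size_cap}")
    tf_rows = ranking[ranking["is_tf"].astype(bool)]
    n_keep = max(1, int(round(len(tf_rows) * tf_fraction))) if len(tf_rows) else 0
    anchors = list(tf_rows["node"].iloc[:n_keep])
    modules: list[Module] = []
    seen_sets: set[frozenset] = set()
    for tf in anchors:
        if tf not in g:
            raise DataError(f"prioritized TF {tf!r} not in network")
        ego = g.subgraph({tf} | set(g[tf]))
        for nodes in enumerate_connected_subgraphs(ego, tf, 3, size_cap, guard):
            if nodes in seen_sets:
                continue
            seen_sets.add(nodes)
            modules.append(Module(f"M{len(modules) + 1:05d}", tf, nodes))
    sizes = pd.Series([m.size for m in modules])
    if len(sizes):
        logger.info(
            "modules per size: %s",
            ", ".join(f"{int(c)} with {int(s)} nodes" for s, c in
                      sizes.value_counts().sort_index().items()),
        )
    return modules


def score_module(module: Module, ranking: pd.DataFrame) -> float:
    """Average module score: mean node strength of the members."""
    strengths = ranking.set_index("node")["node_strength"]
    missing = [n for n in module.nodes if n not in strengths.index]
    if missing:
        raise DataError(f"module {module.module_id}: members missing from ranking: {missing}")
    return float(strengths.loc[list(module.nodes)].mean())


def module_tf_pvalue(
    population: int, successes: int, draws: int, k: int
) -> float:
    """p = 1 − Σ_{i=0}^{k−1} pmf(i) under a hypergeometric mass.

    k = 0 gives exactly 1 (empty sum); k beyond the support's upper end gives
    0. Infeasible parameters raise a domain error naming the constraint.
    """
    if k < 0:
        raise DataError(f"threshold k must be non-negative, got {k}")
    return hypergeom_complement_cdf(k, population, successes, draws)


def module_significance(
    g: nx.Graph,
    modules: Sequence[Module],
    binding: str = "literal",
) -> dict[str, ModuleSignificance]:
    """Per-module anchor-TF significance under a named parameter binding.

    Bindings (all recorded in every result):

    - ``literal``: population = N network nodes, successes = S modules not
      containing the TF, draws = C module size, k = I modules containing the
      TF. Feasible only while S ≤ N.
    - ``modules``: population = S + I (all modules), successes = I, draws =
      min(C, S + I), k = observed module count overlap (I truncated to the
      support).
    - ``tf-content``: population = N, successes = number of TF nodes, draws =
      C, k = number of TFs inside the module. Always feasible; asks whether
      the module holds more TFs than chance.
    """
    if binding not in BINDINGS:
        raise ConfigError(f"unknown binding {binding!r}; choose from {BINDINGS}")
    n_nodes = g.number_of_nodes()
    n_tf = sum(1 for n in g.nodes if g.nodes[n].get("is_tf"))
    containing: dict[str, int] = {}
    for m in modules:
        for tf in {n for n in m.nodes if g.nodes[n].get("is_tf")}:
            containing[tf] = containing.get(tf, 0) + 1
    out: dict[str, ModuleSignificance] = {}
    total_modules = len(modules)
    for m in modules:
        i_count = containing.get(m.anchor_tf, 0)
        s_count = total_modules - i_count
        if binding == "literal":
            pop, succ, draws, k = n_nodes, s_count, m.size, i_count
        elif binding == "modules":
            pop, succ = total_modules, i_count
            draws = min(m.size, total_modules)
            k = min(i_count, min(succ, draws))
        else:  # tf-content
            pop, succ, draws = n_nodes, n_tf, m.size
            k = sum(1 for n in m.nodes if g.nodes[n].get("is_tf"))
        p = module_tf_pvalue(pop, succ, draws, k)
        out[m.module_id] = ModuleSignificance(
            m.anchor_tf, m.module_id, p, binding, pop, succ, draws, k
        )
    return out


def rank_modules(
    modules: Sequence[Module],
    scores: Mapping[str, float],
    significances: Mapping[str, ModuleSignificance],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Filter modules whose anchor-TF p-value is below α and rank them by
    average score, descending, within each size class."""
    rows = []
    for m in modules:
        sig = significances[m.module_id]
        rows.append(
            {
                "module_id": m.module_id,
                "anchor_tf": m.anchor_tf,
                "size": m.size,
                "members": ";".join(sorted(m.nodes)),
                "score": scores[m.module_id],
                "p_value": sig.p_value,
                "binding": sig.binding,
                "significant": sig.p_value < alpha,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "module_id", "anchor_tf", "size", "members",
            "score", "p_value", "binding", "significant",
        ],
    )
    df = df[df["significant"]].drop(columns=["significant"])
    df = df.sort_values(
        ["size", "score", "module_id"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank_in_size_class"] = df.groupby("size").cumcount() + 1
    return df


def size_summary(modules: Sequence[Module]) -> pd.DataFrame:
    """Per-size module counts (the "70 modules with 3 nodes" style table)."""
    sizes = pd.Series([m.size for m in modules], dtype=int)
    counts = sizes.value_counts().sort_index()
    return pd.DataFrame({"size": counts.index, "n_modules": counts.values})
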