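"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: hypergeometric masses
come from exact rational arithmetic and from exhaustive enumeration of
draws, topology metrics from direct BFS path counting and triangle counting,
and structure scores from an O(n^2) all-pairs distance scan.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def hypergeom_pmf_exact(k: int, population: int, successes: int, draws: int) -> Fraction:
    """Exact rational hypergeometric point mass."""
    lo = max(0, draws - (population - successes))
    hi = min(successes, draws)
    if not lo <= k <= hi:
        return Fraction(0)
    return Fraction(
        math.comb(successes, k) * math.comb(population - successes, draws - k),
        math.comb(population, draws),
    )


def hypergeom_tail_exact(k: int, population: int, successes: int, draws: int) -> Fraction:
    """Exact rational upper tail P(X >= k)."""
    hi = min(successes, draws)
    return sum(
        (hypergeom_pmf_exact(i, population, successes, draws) for i in range(max(k, 0), hi + 1)),
        Fraction(0),
    )


def overlap_distribution_by_enumeration(population: int, successes: int, draws: int):
    """Distribution of |draw ∩ marked| over every possible draw, by explicit
    enumeration of all C(population, draws) subsets."""
    marked = set(range(successes))
    counts: dict[int, int] = {}
    total = 0
    for draw in itertools.combinations(range(population), draws):
        m = len(marked.intersection(draw))
        counts[m] = counts.get(m, 0) + 1
        total += 1
    return {m: Fraction(c, total) for m, c in counts.items()}


def association_matrix_bruteforce(weights: np.ndarray) -> np.ndarray:
    """Double loop over documents and term pairs (no linear algebra)."""
    n_docs, n_terms = weights.shape
    out = np.zeros((n_terms, n_terms))
    for k in range(n_terms):
        for l in range(n_terms):
            if k == l:
                continue
            for i in range(n_docs):
                out[k, l] += weights[i, k] * weights[i, l]
    return out


def betweenness_bruteforce(adj: dict) -> dict:
    """Raw betweenness by explicit shortest-path enumeration (BFS counting)."""
    nodes = sorted(adj)
    bet = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS from s: distances and path counts
        dist = {s: 0}
        sigma = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        sigma[w] = 0
                        nxt.append(w)
                    if dist[w] == dist[u] + 1:
                        sigma[w] += sigma[u]
            frontier = nxt
        if t not in dist:
            continue
        # paths through v: sigma(s,v)*sigma(v,t) for v on some shortest path
        for v in nodes:
            if v in (s, t) or v not in dist:
                continue
            # BFS from t for sigma(v, t)
            dist_t = {t: 0}
            sigma_t = {t: 1}
            frontier = [t]
            while frontier:
                nxt = []
                for u in frontier:
                    for w in adj[u]:
                        if w not in dist_t:
                            dist_t[w] = dist_t[u] + 1
                            sigma_t[w] = 0
                            nxt.append(w)
                        if dist_t[w] == dist_t[u] + 1:
                            sigma_t[w] += sigma_t[u]
                frontier = nxt
            if dist[v] + dist_t.get(v, 10**9) == dist[t]:
                bet[v] += sigma[v] * sigma_t[v] / sigma[t]
    return bet


def clustering_bruteforce(adj: dict) -> dict:
    """C_i = 2 n / (k_i (k_i - 1)) by direct neighbor-pair counting."""
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        n_connected = sum(
            1 for a, b in itertools.combinations(sorted(nbrs), 2) if b in adj[a]
        )
        out[v] = 2.0 * n_connected / (k * (k - 1))
    return out


def structure_score_bruteforce(
    coords_a: np.ndarray,
    pred_a: list[int],
    coords_b: np.ndarray,
    pred_b: list[int],
    threshold: float,
):
    """Eq-style interface score by an explicit all-pairs distance loop.

    ``pred_*`` are row indices into the coordinate arrays.
    """
    interacting = 0
    for i in pred_a:
        if any(
            math.dist(coords_a[i], coords_b[j]) <= threshold for j in pred_b
        ):
            interacting += 1
    for j in pred_b:
        if any(
            math.dist(coords_b[j], coords_a[i]) <= threshold for i in pred_a
        ):
            interacting += 1
    probable = len(pred_a) + len(pred_b)
    return interacting, probable


def connected_subgraphs_bruteforce(adj: dict, root, min_size: int, max_size: int):
    """All connected induced subgraphs containing ``root``, by enumerating
    every node subset and checking connectivity with a BFS."""
    nodes = sorted(adj)
    out = set()
    for size in range(min_size, max_size + 1):
        for combo in itertools.combinations(nodes, size):
            if root not in combo:
                continue
            sub = set(combo)
            seen = {root}
            stack = [root]
            while stack:
                u = stack.pop()
                for w in adj[u]:
                    if w in sub and w not in seen:
                        seen.add(w)
                        stack.append(w)
            if seen == sub:
                out.add(frozenset(combo))
    return out
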