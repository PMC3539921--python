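"""Log-space hypergeometric primitives shared by the three statistical stages.

All three significance computations in the pipeline — node–node association,
per-TF module significance, and pathway enrichment — are hypergeometric
probabilities over a finite background. They are evaluated here in
log-factorial space (via the log-gamma function) so that backgrounds of 10^4
and more do not overflow, with tails accumulated by log-sum-exp.

Conventions: a population of ``population`` items contains ``successes``
marked items; ``draws`` items are sampled without replacement; ``k`` marked
items are observed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import DataError

__all__ = [
    "log_binom",
    "hypergeom_log_pmf",
    "hypergeom_pmf",
    "hypergeom_upper_tail",
    "hypergeom_complement_cdf",
    "pair_association_pvalue",
]


def _validate(population: int, successes: int, draws: int) -> None:
    if population < 0 or successes < 0 or draws < 0:
        raise DataError("hypergeometric parameters must be non-negative")
    if successes > population:
        raise DataError(
            f"successes ({successes}) exceed population ({population})"
        )
    if draws > population:
        raise DataError(f"draws ({draws}) exceed population ({population})")


def log_binom(n, k):
    """log of the binomial coefficient C(n, k), vectorized."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_log_pmf(k, population: int, successes: int, draws: int):
    """Log point mass P(X = k) for the hypergeometric distribution.

    Returns ``-inf`` outside the support.
    """
    _validate(population, successes, draws)
    k = np.asarray(k, dtype=float)
    lo = max(0, draws - (population - successes))
    hi = min(successes, draws)
    with np.errstate(invalid="ignore"):
        lp = (
            log_binom(successes, k)
            + log_binom(population - successes, draws - k)
            - log_binom(population, draws)
        )
    return np.where((k >= lo) & (k <= hi), lp, -np.inf)


def hypergeom_pmf(k, population: int, successes: int, draws: int):
    """Point mass P(X = k); exact support handling, log-space evaluation."""
    return np.exp(hypergeom_log_pmf(k, population, successes, draws))


def hypergeom_upper_tail(k: int, population: int, successes: int, draws: int) -> float:
    """Upper tail P(X >= k), accumulated by log-sum-exp over the support."""
    _validate(population, successes, draws)
    hi = min(successes, draws)
    lo = max(0, draws - (population - successes))
    if k > hi:
        return 0.0
    if k <= lo:
        return 1.0  # whole support: exactly one, no round-off
    ks = np.arange(k, hi + 1)
    return float(np.exp(logsumexp(hypergeom_log_pmf(ks, population, successes, draws))))


def hypergeom_complement_cdf(k: int, population: int, successes: int, draws: int) -> float:
    """1 − P(X <= k−1) = P(X >= k); identical tail, named for the module test."""
    return hypergeom_upper_tail(k, population, successes, draws)


def pair_association_pvalue(n1: int, n2: int, m: int, total: int) -> float:
    """Point probability that two nodes with ``n1`` and ``n2`` neighbors among
    ``total`` share exactly ``m`` of them.

    This equals the classical hypergeometric mass
    C(n1, m) · C(total − n1, n2 − m) / C(total, n2).
    """
    if m < 0 or m > min(n1, n2):
        raise DataError(f"shared count m={m} outside [0, min(n1, n2)]")
    if n1 > total or n2 > total:
        raise DataError("neighbor counts exceed the background size")
    if total - n1 - n2 + m < 0:
        raise DataError(
            f"infeasible overlap: total - n1 - n2 + m = {total - n1 - n2 + m} < 0"
        )
    return float(hypergeom_pmf(m, total, n1, n2))
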