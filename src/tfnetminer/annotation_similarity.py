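"""Gene Ontology annotation distance between proteins and TF flagging.

Protein pairs are compared by the Czekanowski-Dice distance on their GO
annotation sets:

    d(A, B) = |A Δ B| / (|A ∪ B| + |A ∩ B|)

with d = 0 for identical sets and d = 1 for disjoint ones. Pairs with
d < 1.0 (at least one shared annotation) are considered GO-supported
interactions. Distances are computed overall and per GO aspect (biological
process, molecular function, cellular component), since per-aspect values
carry independent signal. The similarity 1 − d is the downstream edge weight.

Transcription factors are flagged by intersection of a protein's annotations
with a configured list of TF-functionality GO terms (TF, TF activator /
co-activator, TF repressor / co-repressor, DNA-binding transcription
activity); the list is data, not code, as term identifiers vary by ontology
release.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")

__all__ = [
    "ASPECTS",
    "GOAnnotationSet",
    "EdgeGoSimilarity",
    "TFFlag",
    "czekanowski_dice",
    "edge_go_similarity",
    "is_go_interacting",
    "classify_tf",
    "read_gaf",
    "read_annotations_tsv",
]


@dataclass(frozen=True)
class GOAnnotationSet:
    """GO annotations of one protein, with the aspect of each term."""

    protein_id: str
    terms: frozenset[str]
    aspect_of: Mapping[str, str] = field(default_factory=dict)

    def aspect_terms(self, aspect: str) -> frozenset[str]:
        if aspect not in ASPECTS:
            raise DataError(f"unknown GO aspect {aspect!r}")
        return frozenset(t for t in self.terms if self.aspect_of.get(t) == aspect)


@dataclass(frozen=True)
class EdgeGoSimilarity:
    """Czekanowski-Dice distance of a protein pair, overall and per aspect.

    An undefined distance (both annotation sets empty for the selected scope)
    is carried as NaN, distinctly from the defined extremes 0 and 1.
    """

    pair: tuple[str, str]
    distance_overall: float
    distance_per_aspect: Mapping[str, float]

    @property
    def similarity(self) -> float:
        return 1.0 - self.distance_overall

    @property
    def undefined(self) -> bool:
        return math.isnan(self.distance_overall)


@dataclass(frozen=True)
class TFFlag:
    protein_id: str
    is_tf: bool
    matched_functionalities: frozenset[str]


def czekanowski_dice(
    a: GOAnnotationSet, b: GOAnnotationSet, aspect: str | None = None
) -> float:
    """Czekanowski-Dice distance |AΔB| / (|A∪B| + |A∩B|) on annotation sets.

    ``aspect`` restricts the comparison to one GO aspect; ``None`` compares
    the full sets. Both sets empty is undefined and returned as NaN.
    """
    ta = a.terms if aspect is None else a.aspect_terms(aspect)
    tb = b.terms if aspect is None else b.aspect_terms(aspect)
    if not ta and not tb:
        return math.nan
    union = len(ta | tb)
    inter = len(ta & tb)
    return (union - inter) / (union + inter)


def edge_go_similarity(a: GOAnnotationSet, b: GOAnnotationSet) -> EdgeGoSimilarity:
    """Distance overall and per aspect for one pair."""
    return EdgeGoSimilarity(
        pair=tuple(sorted((a.protein_id, b.protein_id))),
        distance_overall=czekanowski_dice(a, b),
        distance_per_aspect={asp: czekanowski_dice(a, b, asp) for asp in ASPECTS},
    )


def is_go_interacting(sim: EdgeGoSimilarity) -> bool:
    """GO-supported interaction rule: distance strictly below 1.0.

    Undefined distances (no annotations on either side) are not interacting.
    """
    if sim.undefined:
        logger.warning("undefined GO distance for pair %s", sim.pair)
        return False
    return sim.distance_overall < 1.0


def classify_tf(annot: GOAnnotationSet, tf_terms: Iterable[str]) -> TFFlag:
    """Flag a protein as TF iff it carries any configured TF-functionality term."""
    tf_terms = frozenset(tf_terms)
    if not tf_terms:
        raise DataError("empty TF functionality term list")
    matched = annot.terms & tf_terms
    return TFFlag(annot.protein_id, bool(matched), matched)


def _assemble(
    rows: list[tuple[str, str, str]], n_skipped: int, source: str
) -> dict[str, GOAnnotationSet]:
    if n_skipped:
        logger.warning("%s: skipped %d malformed lines", source, n_skipped)
    terms: dict[str, set[str]] = {}
    aspects: dict[str, dict[str, str]] = {}
    for pid, term, asp in rows:
        terms.setdefault(pid, set()).add(term)
        aspects.setdefault(pid, {})[term] = asp
    return {
        pid: GOAnnotationSet(pid, frozenset(ts), aspects[pid])
        for pid, ts in terms.items()
    }


def read_gaf(path: str | Path) -> dict[str, GOAnnotationSet]:
    """Read a GAF 2.x file (columns 2, 5, 9: object id, GO id, aspect).

    GAF aspect codes P/F/C are mapped to BP/MF/CC. Malformed lines are
    skipped and counted in the log.
    """
    aspect_map = {"P": "BP", "F": "MF", "C": "CC"}
    rows: list[tuple[str, str, str]] = []
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("!"):
            continue
        parts = line.split("\t")
        if len(parts) < 9 or not parts[4].startswith("GO:") or parts[8] not in aspect_map:
            skipped += 1
            continue
        rows.append((parts[1], parts[4], aspect_map[parts[8]]))
    if not rows:
        raise DataError(f"no usable annotation lines in {path}")
    return _assemble(rows, skipped, str(path))


def read_annotations_tsv(path: str | Path) -> dict[str, GOAnnotationSet]:
    """Read the simple 3-column alternative: protein <TAB> GO id <TAB> aspect."""
    rows: list[tuple[str, str, str]] = []
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3 or parts[2] not in ASPECTS:
            skipped += 1
            continue
        rows.append((parts[0], parts[1], parts[2]))
    if not rows:
        raise DataError(f"no usable annotation lines in {path}")
    return _assemble(rows, skipped, str(path))


def distance_table(sims: Iterable[EdgeGoSimilarity]) -> pd.DataFrame:
    """Tabulate pairwise distances for output."""
    rows = [
        {
            "protein_a": s.pair[0],
            "protein_b": s.pair[1],
            "distance": s.distance_overall,
            "similarity": s.similarity,
            **{f"distance_{a.lower()}": s.distance_per_aspect[a] for a in ASPECTS},
        }
        for s in sims
    ]
    return pd.DataFrame(rows)
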