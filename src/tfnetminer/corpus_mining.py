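"""Literature co-occurrence mining: tf*idf gene-term vectors, the gene–gene
association matrix, thresholding, and typed relation extraction.

A corpus of abstracts is converted to M-dimensional weight vectors over a gene
thesaurus, one vector per document, with the weight of term *k* in document
*i* given by tf*idf:

    W_ik = T_ik * log(N / n_k)

where ``T_ik`` is the in-document frequency of any synonym of term *k*, ``N``
the corpus size, and ``n_k`` the number of documents mentioning term *k*.
The association between two terms is the dot product of their weight columns
across documents; associations at or above a threshold are retained as
candidate interactions, and retained pairs are typed by counting sentences in
which both genes co-occur with a trigger word from a relation thesaurus.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ThesaurusError

__all__ = [
    "Document",
    "GeneThesaurus",
    "RelationThesaurus",
    "TermVectorSet",
    "AssociationMatrix",
    "RelationAssignment",
    "read_corpus_jsonl",
    "read_corpus_dir",
    "build_term_vectors",
    "compute_association_matrix",
    "threshold_associations",
    "extract_relations",
    "DEFAULT_SENTENCE_PATTERN",
]

#: Sentence boundary: terminal punctuation, whitespace, then an uppercase
#: letter or digit. Deterministic and dependency-free; configurable.
DEFAULT_SENTENCE_PATTERN = r"(?<=[.!?])\s+(?=[A-Z0-9])"


@dataclass(frozen=True)
class Document:
    """One corpus record (an abstract)."""

    doc_id: str
    text: str
    sentence_pattern: str = DEFAULT_SENTENCE_PATTERN

    @cached_property
    def sentences(self) -> tuple[str, ...]:
        """Sentence strings; the spans partition the text non-overlappingly."""
        parts = re.split(self.sentence_pattern, self.text)
        return tuple(p for p in parts if p.strip())


class GeneThesaurus:
    """Canonical gene ids and their synonyms, with a longest-first matcher.

    Matching is case-insensitive on token boundaries; overlapping candidate
    matches are resolved left-to-right with the longest synonym winning at
    each position.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, frozenset[str]] = {}
        self._syn_to_id: dict[str, str] = {}
        for cid, syns in entries.items():
            syns = frozenset(s.strip() for s in syns if s.strip())
            if not syns:
                raise ThesaurusError(f"gene {cid!r} has no synonyms")
            self.entries[cid] = syns
            for s in syns:
                key = s.lower()
                prev = self._syn_to_id.get(key)
                if prev is not None and prev != cid:
                    raise ThesaurusError(
                        f"synonym {s!r} maps to both {prev!r} and {cid!r}"
                    )
                self._syn_to_id[key] = cid
        if not self.entries:
            raise ThesaurusError("empty gene thesaurus")
        ordered = sorted(self._syn_to_id, key=lambda s: (-len(s), s))
        self._pattern = re.compile(
            r"\b(?:" + "|".join(re.escape(s) for s in ordered) + r")\b",
            re.IGNORECASE,
        )

    @property
    def M(self) -> int:
        """Number of gene terms (canonical ids)."""
        return len(self.entries)

    @property
    def terms(self) -> list[str]:
        return sorted(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneThesaurus":
        """Load a two-column TSV: canonical_id <TAB> synonym, one per line."""
        entries: dict[str, set[str]] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ThesaurusError(f"{path}:{ln}: expected 2 columns")
            entries.setdefault(parts[0].strip(), set()).add(parts[1].strip())
        return cls(entries)

    def find_terms(self, text: str) -> list[str]:
        """Canonical ids matched in ``text``, in match order (with repeats)."""
        return [self._syn_to_id[m.group(0).lower()] for m in self._pattern.finditer(text)]


class RelationThesaurus:
    """Relation labels and their lower-cased trigger words."""

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, frozenset[str]] = {}
        seen: dict[str, str] = {}
        for label, triggers in entries.items():
            trig = frozenset(t.strip().lower() for t in triggers if t.strip())
            for t in trig:
                if t in seen:
                    raise ThesaurusError(
                        f"trigger {t!r} appears under both {seen[t]!r} and {label!r}"
                    )
                seen[t] = label
            self.entries[label] = trig
        all_triggers = sorted(seen, key=lambda s: (-len(s), s))
        self._pattern = re.compile(
            r"\b(?:" + "|".join(re.escape(t) for t in all_triggers) + r")\b",
            re.IGNORECASE,
        ) if all_triggers else None
        self._trig_to_label = seen

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelationThesaurus":
        entries: dict[str, set[str]] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ThesaurusError(f"{path}:{ln}: expected 2 columns")
            entries.setdefault(parts[0].strip(), set()).add(parts[1].strip())
        return cls(entries)

    def labels_in(self, text: str) -> set[str]:
        """Relation labels triggered anywhere in ``text``."""
        if self._pattern is None:
            return set()
        return {
            self._trig_to_label[m.group(0).lower()]
            for m in self._pattern.finditer(text)
        }


@dataclass
class TermVectorSet:
    """tf*idf document vectors over the thesaurus terms."""

    terms: list[str]
    doc_ids: list[str]
    term_freq: np.ndarray  # (N, M) raw counts T_ik
    doc_freq: np.ndarray  # (M,) n_k
    weights: np.ndarray  # (N, M) W_ik
    log_base: float

    @property
    def N(self) -> int:
        return len(self.doc_ids)


@dataclass
class AssociationMatrix:
    """Symmetric term×term association scores with an optional threshold."""

    terms: list[str]
    scores: np.ndarray  # (M, M), symmetric, zero diagonal
    threshold: float | None = None
    retained_pairs: set[tuple[str, str]] = field(default_factory=set)

    def score(self, a: str, b: str) -> float:
        i, j = self.terms.index(a), self.terms.index(b)
        return float(self.scores[i, j])


@dataclass
class RelationAssignment:
    """Typed relation evidence for one retained gene pair."""

    pair: tuple[str, str]
    per_relation_score: dict[str, int]
    best_relation: str | None


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    """Read a JSON-lines corpus; each line an object with ``id`` and ``text``."""
    docs: list[Document] = []
    seen: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise DataError(f"{path}:{ln}: invalid JSON: {exc}") from exc
        if "id" not in obj or "text" not in obj:
            raise DataError(f"{path}:{ln}: record must have 'id' and 'text'")
        did = str(obj["id"])
        if did in seen:
            raise DataError(f"{path}:{ln}: duplicate doc_id {did!r}")
        seen.add(did)
        docs.append(Document(did, str(obj["text"])))
    return docs


def read_corpus_dir(path: str | Path) -> list[Document]:
    """Read a directory of plain-text abstracts named ``<id>.txt``."""
    docs = [
        Document(p.stem, p.read_text())
        for p in sorted(Path(path).glob("*.txt"))
    ]
    if not docs:
        raise DataError(f"no *.txt files under {path}")
    return docs


def build_term_vectors(
    corpus: Sequence[Document],
    thesaurus: GeneThesaurus,
    log_base: float = 10.0,
    binary_tf: bool = False,
) -> TermVectorSet:
    """Compute tf*idf weight vectors W_ik = T_ik · log(N / n_k).

    ``T_ik`` is the raw count of synonym occurrences of term *k* in document
    *i* (or 0/1 when ``binary_tf``). Terms occurring in every document get
    weight 0 (log N/N), as do terms absent from a document. Terms absent from
    the whole corpus yield all-zero columns.
    """
    if not corpus:
        raise DataError("empty corpus")
    if log_base <= 0 or log_base == 1:
        raise ConfigError(f"invalid log base {log_base}")
    terms = thesaurus.terms
    idx = {t: k for k, t in enumerate(terms)}
    tf = np.zeros((len(corpus), len(terms)), dtype=float)
    for i, doc in enumerate(corpus):
        for cid in thesaurus.find_terms(doc.text):
            tf[i, idx[cid]] += 1.0
    if binary_tf:
        tf = (tf > 0).astype(float)
    df = (tf > 0).sum(axis=0)
    n = len(corpus)
    with np.errstate(divide="ignore"):
        idf = np.where(df > 0, np.log(n / np.maximum(df, 1)) / math.log(log_base), 0.0)
    return TermVectorSet(
        terms=terms,
        doc_ids=[d.doc_id for d in corpus],
        term_freq=tf,
        doc_freq=df,
        weights=tf * idf,
        log_base=log_base,
    )


def compute_association_matrix(vectors: TermVectorSet) -> AssociationMatrix:
    """Association of terms k, l: Σ_i W_ik · W_il (diagonal zeroed)."""
    scores = vectors.weights.T @ vectors.weights
    np.fill_diagonal(scores, 0.0)
    return AssociationMatrix(terms=list(vectors.terms), scores=scores)


def threshold_associations(
    matrix: AssociationMatrix, threshold: float | None = None
) -> set[tuple[str, str]]:
    """Retain unordered pairs with score >= threshold.

    With ``threshold=None`` the default is the 95th percentile of the non-zero
    off-diagonal scores (a scale-free choice, since the association scale
    depends on corpus size). Zero-score pairs are never retained, including at
    threshold 0. The retained set and threshold are recorded on ``matrix``.
    """
    if threshold is not None and threshold < 0:
        raise ConfigError(f"negative association threshold {threshold}")
    iu = np.triu_indices(len(matrix.terms), k=1)
    vals = matrix.scores[iu]
    nonzero = vals[vals > 0]
    if threshold is None:
        threshold = float(np.percentile(nonzero, 95.0)) if nonzero.size else 0.0
    keep = (vals >= threshold) & (vals > 0)
    pairs = {
        tuple(sorted((matrix.terms[i], matrix.terms[j])))
        for i, j in zip(iu[0][keep], iu[1][keep])
    }
    matrix.threshold = threshold
    matrix.retained_pairs = pairs
    return pairs


def extract_relations(
    corpus: Sequence[Document],
    pair: tuple[str, str],
    thesaurus: GeneThesaurus,
    relations: RelationThesaurus,
) -> RelationAssignment:
    """Count, per relation label, sentences mentioning both genes of ``pair``
    together with one of the label's trigger words.

    The best relation is the argmax count; ties break to the lexicographically
    smallest label; all-zero counts yield no relation.
    """
    a, b = pair
    counts: dict[str, int] = {label: 0 for label in relations.entries}
    for doc in corpus:
        for sent in doc.sentences:
            present = set(thesaurus.find_terms(sent))
            if a in present and b in present:
                for label in relations.labels_in(sent):
                    counts[label] += 1
    best: str | None = None
    if any(counts.values()):
        best = min(
            (label for label, c in counts.items() if c == max(counts.values())),
        )
    return RelationAssignment(pair=tuple(sorted(pair)), per_relation_score=counts, best_relation=best)


def association_table(
    matrix: AssociationMatrix,
    relations_by_pair: Mapping[tuple[str, str], RelationAssignment] | None = None,
) -> pd.DataFrame:
    """Tabulate retained pairs with scores and best relations."""
    rows = []
    for pair in sorted(matrix.retained_pairs):
        a, b = pair
        rel = relations_by_pair.get(pair) if relations_by_pair else None
        best = rel.best_relation if rel else None
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "score": matrix.score(a, b),
                "best_relation": best if best is not None else "",
                "relation_score": (
                    rel.per_relation_score.get(best, 0) if rel and best else 0
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "score", "best_relation", "relation_score"]
    )
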