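"""Structure-based protein-protein interaction calls from C-alpha geometry.

For a protein pair with solved structures, interaction support is computed in
six steps: map each protein to its chains, predict probable interface
residues per chain from residue physico-chemical properties, measure C-alpha
distances between the predicted residues of the two chains, count a predicted
residue as interacting when its C-alpha lies within a distance threshold
(default 6 Å) of any predicted residue of the partner, score the structure
pair by

    interaction_score = n_interacting / n_probable

over the union of both chains' predicted residues (satisfying when the score
reaches the 10% minimum), and call the protein pair interacting when at least
30% of its structure pairs satisfy those conditions. Both thresholds are
inclusive (≥). Proteins with no mapped structures yield a distinct
"no structural evidence" outcome rather than a negative call.

The interface predictor is pluggable; the default scores each residue by a
hydrophobicity table combined with a centroid-distance exposure proxy, which
is deterministic and requires no external method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "ChainStructure",
    "InterfacePrediction",
    "StructurePairResult",
    "PairInteractionCall",
    "HydrophobicityExposurePredictor",
    "AllResiduesPredictor",
    "predict_interface_residues",
    "structure_pair_score",
    "pair_interaction_call",
    "read_chain",
    "read_structure_map",
    "KYTE_DOOLITTLE",
]

#: Kyte-Doolittle residue hydropathy (three-letter codes).
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
_KD_MIN, _KD_MAX = min(KYTE_DOOLITTLE.values()), max(KYTE_DOOLITTLE.values())


@dataclass(frozen=True)
class Residue:
    index: int
    restype: str
    ca: tuple[float, float, float]


@dataclass
class ChainStructure:
    """One chain's C-alpha trace, keyed to a protein."""

    structure_id: str
    protein_id: str
    residues: list[Residue]
    n_missing_ca: int = 0  # residues skipped for unresolved C-alpha

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise DataError(
                f"{self.structure_id}: residue indices not strictly increasing"
            )
        if self.residues and not np.all(np.isfinite(self.coords)):
            raise DataError(f"{self.structure_id}: non-finite C-alpha coordinate")

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class InterfacePrediction:
    structure_id: str
    predicted_residues: frozenset[int]


@dataclass(frozen=True)
class StructurePairResult:
    """One structure pair's interface agreement (undefined score when no
    residues were predicted on either chain)."""

    pair: tuple[str, str]
    interacting_count: int
    probable_count: int
    interaction_score: float | None
    satisfies: bool


@dataclass(frozen=True)
class PairInteractionCall:
    """Aggregated call over all structure pairs of a protein pair.

    ``is_interacting`` is None when there is no structural evidence at all.
    ``mean_interaction_score`` (mean of defined per-structure scores) is the
    structural edge weight used downstream.
    """

    pair: tuple[str, str]
    n_structures: int
    n_satisfying: int
    structure_fraction: float | None
    is_interacting: bool | None
    mean_interaction_score: float | None = None

    @property
    def no_structural_evidence(self) -> bool:
        return self.n_structures == 0


class InterfacePredictor(Protocol):
    def predict(self, chain: ChainStructure) -> InterfacePrediction: ...


@dataclass(frozen=True)
class HydrophobicityExposurePredictor:
    """Default deterministic interface predictor.

    Each residue is scored as w_h · hydrophobicity + w_e · exposure, where
    hydrophobicity is the table value min-max scaled to [0, 1] and exposure
    is the residue's distance from the chain centroid divided by the maximum
    such distance (1.0 for a single-residue chain). Residues scoring at or
    above ``cutoff`` are predicted as probable interface residues.
    """

    cutoff: float = 0.5
    w_hydrophobicity: float = 0.5
    w_exposure: float = 0.5
    table: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))

    def predict(self, chain: ChainStructure) -> InterfacePrediction:
        if not chain.residues:
            return InterfacePrediction(chain.structure_id, frozenset())
        coords = chain.coords
        centroid = coords.mean(axis=0)
        dists = np.linalg.norm(coords - centroid, axis=1)
        dmax = dists.max()
        exposure = dists / dmax if dmax > 0 else np.ones_like(dists)
        lo, hi = min(self.table.values()), max(self.table.values())
        span = hi - lo or 1.0
        hydro = np.array(
            [(self.table.get(r.restype, lo) - lo) / span for r in chain.residues]
        )
        score = self.w_hydrophobicity * hydro + self.w_exposure * exposure
        keep = frozenset(
            r.index for r, s in zip(chain.residues, score) if s >= self.cutoff
        )
        return InterfacePrediction(chain.structure_id, keep)


class AllResiduesPredictor:
    """Trivial predictor that marks every residue probable (for testing and
    for structures where no physico-chemical screen is wanted)."""

    def predict(self, chain: ChainStructure) -> InterfacePrediction:
        return InterfacePrediction(
            chain.structure_id, frozenset(r.index for r in chain.residues)
        )


def predict_interface_residues(
    chain: ChainStructure, predictor: InterfacePredictor | None = None
) -> InterfacePrediction:
    """Predict probable interface residues; empty chain gives an empty set."""
    predictor = predictor or HydrophobicityExposurePredictor()
    pred = predictor.predict(chain)
    extra = pred.predicted_residues - {r.index for r in chain.residues}
    if extra:
        raise DataError(f"predictor returned unknown residues {sorted(extra)}")
    return pred


def structure_pair_score(
    chain_a: ChainStructure,
    pred_a: InterfacePrediction,
    chain_b: ChainStructure,
    pred_b: InterfacePrediction,
    distance_threshold: float = 6.0,
    min_fraction: float = 0.10,
) -> StructurePairResult:
    """Score one structure pair: fraction of predicted residues (union of both
    chains) whose C-alpha lies within ``distance_threshold`` of a predicted
    residue of the partner chain."""
    by_idx_a = {r.index: r.ca for r in chain_a.residues}
    by_idx_b = {r.index: r.ca for r in chain_b.residues}
    ca = np.array([by_idx_a[i] for i in sorted(pred_a.predicted_residues)]).reshape(-1, 3)
    cb = np.array([by_idx_b[i] for i in sorted(pred_b.predicted_residues)]).reshape(-1, 3)
    probable = len(ca) + len(cb)
    pair = (chain_a.structure_id, chain_b.structure_id)
    if probable == 0:
        logger.warning("no probable interface residues for structure pair %s", pair)
        return StructurePairResult(pair, 0, 0, None, False)
    if len(ca) and len(cb):
        d = cdist(ca, cb)
        interacting = int((d.min(axis=1) <= distance_threshold).sum()) + int(
            (d.min(axis=0) <= distance_threshold).sum()
        )
    else:
        interacting = 0
    score = interacting / probable
    return StructurePairResult(pair, interacting, probable, score, score >= min_fraction)


def pair_interaction_call(
    pair: tuple[str, str],
    results: Sequence[StructurePairResult],
    structure_fraction_threshold: float = 0.30,
) -> PairInteractionCall:
    """Aggregate structure-pair results into one protein-pair call: interacting
    when the satisfying fraction reaches the threshold (inclusive)."""
    pair = tuple(sorted(pair))
    if not results:
        return PairInteractionCall(pair, 0, 0, None, None, None)
    n = len(results)
    n_sat = sum(r.satisfies for r in results)
    frac = n_sat / n
    defined = [r.interaction_score for r in results if r.interaction_score is not None]
    mean_score = float(np.mean(defined)) if defined else None
    return PairInteractionCall(
        pair, n, n_sat, frac, frac >= structure_fraction_threshold, mean_score
    )


def read_chain(
    path: str | Path,
    chain_id: str | None = None,
    protein_id: str = "",
    structure_id: str | None = None,
) -> ChainStructure:
    """Read one chain's C-alpha trace from a PDB-format coordinate file.

    Only ATOM coordinate records are considered (polymer residues); residues
    without a resolved C-alpha are skipped and counted. Default chain: first
    in the file.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise DataError(f"{path}: no models")
    model = st[0]
    chain = None
    if chain_id is None:
        chain = model[0] if len(model) else None
    else:
        for c in model:
            if c.name == chain_id:
                chain = c
                break
    if chain is None:
        raise DataError(f"{path}: chain {chain_id!r} not found")
    sid = structure_id or f"{Path(path).stem}_{chain.name}"
    residues: list[Residue] = []
    missing = 0
    for res in chain:
        if res.het_flag == "H":
            continue
        ca = res.find_atom("CA", "*")
        if ca is None:
            missing += 1
            continue
        residues.append(
            Residue(res.seqid.num, res.name, (ca.pos.x, ca.pos.y, ca.pos.z))
        )
    if missing:
        logger.info("%s chain %s: %d residues without C-alpha", path, chain.name, missing)
    return ChainStructure(sid, protein_id, residues, n_missing_ca=missing)


def read_structure_map(path: str | Path) -> list[tuple[str, str, str]]:
    """Read the mapping TSV: protein_id <TAB> pdb_id <TAB> chain."""
    rows: list[tuple[str, str, str]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise DataError(f"{path}:{ln}: expected 3 columns")
        rows.append((parts[0], parts[1], parts[2]))
    return rows


def call_table(calls: Sequence[PairInteractionCall]) -> pd.DataFrame:
    rows = [
        {
            "protein_a": c.pair[0],
            "protein_b": c.pair[1],
            "n_structures": c.n_structures,
            "n_satisfying": c.n_satisfying,
            "structure_fraction": c.structure_fraction,
            "is_interacting": c.is_interacting,
            "mean_interaction_score": c.mean_interaction_score,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
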