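"""Hypergeometric pathway enrichment with functional-group classification.

Given a protein list of size R and a pathway with n genes in a background of
N genes, the enrichment p-value is the upper hypergeometric tail

    p(r, n, R, N) = Σ_{i = max(r, R+n−N)}^{min(n, R)} P(i; n, R, N),

i.e. the probability of an overlap at least as large as the observed r,
evaluated in log-factorial space. Pathways below α are flagged significant.
Pathways optionally carry functional-group labels; a group is classified
"major" when it holds more than 3 significant pathways and "minor"
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from gseapy import read_gmt
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .hypergeom import hypergeom_upper_tail

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDB",
    "EnrichmentResult",
    "enrich_pathways",
    "classify_functional_groups",
]


@dataclass
class PathwayDB:
    """Pathway gene sets, optional group labels, and the enrichment background.

    Default background: the union of all pathway genes (overridable).
    """

    pathways: dict[str, frozenset[str]]
    groups: Mapping[str, str] = field(default_factory=dict)
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.pathways:
            raise DataError("empty pathway collection")
        for pid, genes in self.pathways.items():
            if not genes:
                raise DataError(f"pathway {pid!r} has no genes")
        union = frozenset().union(*self.pathways.values())
        if self.background is None:
            self.background = union
        else:
            self.background = frozenset(self.background)
            if not union <= self.background:
                raise DataError("background does not cover all pathway genes")

    @property
    def n_background(self) -> int:
        return len(self.background)

    @classmethod
    def from_gmt(
        cls,
        gmt_path: str | Path,
        groups_tsv: str | Path | None = None,
        background: Iterable[str] | None = None,
    ) -> "PathwayDB":
        """Load a standard GMT file and an optional pathway→group TSV."""
        sets = {
            name: frozenset(genes)
            for name, genes in read_gmt(str(gmt_path)).items()
        }
        groups: dict[str, str] = {}
        if groups_tsv is not None:
            for ln, line in enumerate(Path(groups_tsv).read_text().splitlines(), 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DataError(f"{groups_tsv}:{ln}: expected 2 columns")
                groups[parts[0]] = parts[1]
        return cls(
            sets, groups,
            frozenset(background) if background is not None else None,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    R: int
    n: int
    r: int
    p_value: float
    significant: bool
    functional_group: str


def enrich_pathways(
    user_list: Iterable[str], db: PathwayDB, alpha: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``user_list`` in every pathway.

    Genes outside the background are dropped (counted in the log). Results
    are sorted ascending by p-value, with a BH q-value column; the
    significance flag uses the raw p-value at α.
    """
    users = set(user_list)
    if not users:
        raise DataError("empty user gene list")
    dropped = users - db.background
    if dropped:
        logger.warning(
            "%d user genes outside the background dropped (e.g. %s)",
            len(dropped), sorted(dropped)[:5],
        )
    users &= db.background
    if not users:
        raise DataError("no user genes remain within the background")
    big_n, big_r = db.n_background, len(users)
    rows = []
    for pid in sorted(db.pathways):
        genes = db.pathways[pid] & db.background
        r = len(users & genes)
        p = hypergeom_upper_tail(r, big_n, len(genes), big_r)
        rows.append(
            {
                "pathway_id": pid,
                "R": big_r,
                "n": len(genes),
                "r": r,
                "p_value": p,
                "significant": p < alpha,
                "functional_group": db.groups.get(pid, "ungrouped"),
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )


def classify_functional_groups(results: pd.DataFrame) -> pd.DataFrame:
    """Count significant pathways per functional group; groups with more than
    3 significant pathways are "major", the rest "minor". Groups without any
    significant pathway are omitted."""
    sig = results[results["significant"]]
    counts = sig.groupby("functional_group").size()
    rows = [
        {
            "functional_group": grp,
            "n_significant_pathways": int(c),
            "classification": "major" if c > 3 else "minor",
        }
        for grp, c in counts.sort_values(ascending=False).items()
    ]
    return pd.DataFrame(
        rows, columns=["functional_group", "n_significant_pathways", "classification"]
    )
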