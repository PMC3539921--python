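"""Six-stage pipeline: data load, association mining, GO/structure
validation, network construction, prioritization + modules, and pathway
enrichment — with a run manifest recording counts and every resolved
methodological choice.

The stages compose on disk: each writes its outputs before the next starts,
all outputs are plain TSV/GraphML/JSON with stable column orders and
formatting, and a rerun with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .annotation_similarity import (
    EdgeGoSimilarity,
    GOAnnotationSet,
    classify_tf,
    distance_table,
    edge_go_similarity,
    read_annotations_tsv,
    read_gaf,
)
from .corpus_mining import (
    AssociationMatrix,
    GeneThesaurus,
    RelationThesaurus,
    association_table,
    build_term_vectors,
    compute_association_matrix,
    extract_relations,
    read_corpus_dir,
    read_corpus_jsonl,
    threshold_associations,
)
from .errors import ConfigError, DataError
from .module_analysis import (
    extract_modules,
    module_significance,
    rank_modules,
    score_module,
    size_summary,
)
from .pathway_enrichment import PathwayDB, classify_functional_groups, enrich_pathways
from .prioritization import PrioritizationConfig, compute_node_features, rank_nodes
from .structure_interaction import (
    HydrophobicityExposurePredictor,
    pair_interaction_call,
    predict_interface_residues,
    read_chain,
    read_structure_map,
    structure_pair_score,
)
from .tf_network import (
    build_network,
    compute_topology,
    edge_table,
    node_table,
    read_id_list,
    tier_evidence,
    write_graphml,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_tsv"]

_P_COLS = ("p_value", "q_value")


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (YAML-loadable).

    Structure inputs and membership lists are optional; everything else is
    required. Unknown keys in the YAML are rejected.
    """

    corpus: str = ""
    gene_thesaurus: str = ""
    relation_thesaurus: str = ""
    annotations: str = ""
    tf_terms: str = ""
    pathways_gmt: str = ""
    out_dir: str = "tfnetminer-run"
    structures_dir: str | None = None
    structure_map: str | None = None
    pathway_groups: str | None = None
    colon_list: str | None = None
    cancer_list: str | None = None
    other_list: str | None = None
    association_threshold: float | None = None
    log_base: float = 10.0
    distance_threshold: float = 6.0
    min_residue_fraction: float = 0.10
    structure_fraction_threshold: float = 0.30
    scheme: str = "weighted"
    module_binding: str = "tf-content"
    module_size_cap: int = 8
    module_tf_fraction: float = 0.5
    alpha_association: float = 0.05
    alpha_module: float = 0.05
    alpha_pathway: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_residue_fraction <= 1:
            raise ConfigError("min_residue_fraction outside (0, 1]")
        if not 0 < self.structure_fraction_threshold <= 1:
            raise ConfigError("structure_fraction_threshold outside (0, 1]")
        if self.distance_threshold <= 0:
            raise ConfigError("distance_threshold must be positive")
        for a in ("alpha_association", "alpha_module", "alpha_pathway"):
            if not 0 <= getattr(self, a) <= 1:
                raise ConfigError(f"{a} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_fixture_dir(
        cls, fixture_dir: str | Path, out_dir: str | Path, **overrides
    ) -> "PipelineConfig":
        """Convenience wiring for a directory produced by the fixture
        generator's standard file layout."""
        d = Path(fixture_dir)
        return cls(
            corpus=str(d / "corpus.jsonl"),
            gene_thesaurus=str(d / "gene_thesaurus.tsv"),
            relation_thesaurus=str(d / "relation_thesaurus.tsv"),
            annotations=str(d / "annotations.tsv"),
            tf_terms=str(d / "tf_terms.txt"),
            structures_dir=str(d / "structures"),
            structure_map=str(d / "structure_map.tsv"),
            pathways_gmt=str(d / "pathways.gmt"),
            pathway_groups=str(d / "pathway_groups.tsv"),
            colon_list=str(d / "colon_list.txt"),
            cancer_list=str(d / "cancer_list.txt"),
            other_list=str(d / "other_list.txt"),
            out_dir=str(out_dir),
            **overrides,
        )


def write_tsv(df: pd.DataFrame, path: str | Path, p_cols: tuple[str, ...] = _P_COLS) -> None:
    """TSV writer with stable formatting: UTF-8, LF, 6 significant digits,
    p-values in scientific notation."""
    out = df.copy()
    for col in out.columns:
        if col in p_cols and pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6e}")
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _require(path: str | None, what: str, stage: str) -> Path:
    if not path:
        raise ConfigError(f"stage {stage}: missing required input ({what})")
    p = Path(path)
    if not p.exists():
        raise DataError(f"stage {stage}: {what} not found: {p}")
    return p


# ---------------------------------------------------------------- stages


def mine_stage(corpus, gene_thes, rel_thes, threshold, log_base):
    """Stage 2: tf*idf vectors, association matrix, thresholding, relations."""
    vectors = build_term_vectors(corpus, gene_thes, log_base=log_base)
    matrix = compute_association_matrix(vectors)
    pairs = threshold_associations(matrix, threshold)
    relations = {
        pair: extract_relations(corpus, pair, gene_thes, rel_thes)
        for pair in sorted(pairs)
    }
    return vectors, matrix, pairs, relations


def go_stage(annots, tf_term_list, pairs):
    """Stage 3a: GO distances for retained pairs and TF flags for all
    annotated proteins. Proteins missing from the annotation source are
    compared with empty sets (distance undefined → pair not interacting)."""
    def get(pid: str) -> GOAnnotationSet:
        return annots.get(pid, GOAnnotationSet(pid, frozenset()))

    sims = {p: edge_go_similarity(get(p[0]), get(p[1])) for p in sorted(pairs)}
    flags = {pid: classify_tf(a, tf_term_list) for pid, a in annots.items()}
    return sims, flags


def structure_stage(
    map_rows, structures_dir, pairs,
    distance_threshold=6.0, min_fraction=0.10, structure_fraction_threshold=0.30,
    predictor=None,
):
    """Stage 3b: structure-pair scores and per-pair interaction calls.

    Chains are compared only within a shared PDB entry (C-alpha distances
    across crystals are not in a common frame); a protein pair's structures
    are all entries mapping both proteins.
    """
    predictor = predictor or HydrophobicityExposurePredictor()
    structures_dir = Path(structures_dir)
    by_entry: dict[str, dict[str, str]] = {}
    for prot, pdb_id, chain in map_rows:
        by_entry.setdefault(pdb_id, {})[prot] = chain
    chain_cache: dict[tuple[str, str], tuple] = {}

    def load(pdb_id: str, prot: str, chain: str):
        key = (pdb_id, chain)
        if key not in chain_cache:
            path = structures_dir / f"{pdb_id.lower()}.pdb"
            if not path.exists():
                path = structures_dir / f"{pdb_id}.pdb"
            ch = read_chain(path, chain, protein_id=prot, structure_id=f"{pdb_id}_{chain}")
            chain_cache[key] = (ch, predict_interface_residues(ch, predictor))
        return chain_cache[key]

    pair_rows = []
    calls = {}
    for pair in sorted(pairs):
        a, b = pair
        results = []
        for pdb_id in sorted(by_entry):
            ent = by_entry[pdb_id]
            if a in ent and b in ent and ent[a] != ent[b]:
                ca, pa = load(pdb_id, a, ent[a])
                cb, pb = load(pdb_id, b, ent[b])
                res = structure_pair_score(
                    ca, pa, cb, pb, distance_threshold, min_fraction
                )
                results.append(res)
                pair_rows.append(
                    {
                        "protein_a": a, "protein_b": b,
                        "structure_a": res.pair[0], "structure_b": res.pair[1],
                        "interacting_count": res.interacting_count,
                        "probable_count": res.probable_count,
                        "interaction_score": res.interaction_score,
                        "satisfies": res.satisfies,
                    }
                )
        call = pair_interaction_call(pair, results, structure_fraction_threshold)
        if call.n_structures:
            calls[pair] = call
    return pd.DataFrame(
        pair_rows,
        columns=[
            "protein_a", "protein_b", "structure_a", "structure_b",
            "interacting_count", "probable_count", "interaction_score", "satisfies",
        ],
    ), calls


# ---------------------------------------------------------------- pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all six stages and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        # out_dir omitted: the manifest lives inside it, and its value must
        # not break byte-identity of otherwise identical runs
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
        },
        "versions": _versions(),
        "counts": {},
        "decisions": {
            "log_base": config.log_base,
            "association_threshold": "95th percentile of non-zero scores"
            if config.association_threshold is None
            else config.association_threshold,
            "tfidf_term_frequency": "raw count",
            "structure_score_denominator": "union of predicted residues of both chains",
            "threshold_comparisons": "inclusive (>=)",
            "structure_pairing": "chains within a shared PDB entry",
            "betweenness_for_scoring": "normalized per component",
            "node_strength_scheme": config.scheme,
            "module_pvalue_binding": config.module_binding,
            "relation_tie_break": "lexicographically smallest label",
            "edge_structural_score": "mean defined per-structure interaction score",
        },
    }

    # Stage 1: data collection -------------------------------------------
    stage = "1-data-load"
    corpus_path = _require(config.corpus, "corpus", stage)
    if corpus_path.is_dir():
        corpus = read_corpus_dir(corpus_path)
    else:
        corpus = read_corpus_jsonl(corpus_path)
    gene_thes = GeneThesaurus.from_tsv(_require(config.gene_thesaurus, "gene thesaurus", stage))
    rel_thes = RelationThesaurus.from_tsv(
        _require(config.relation_thesaurus, "relation thesaurus", stage)
    )
    manifest["counts"]["documents"] = len(corpus)
    manifest["counts"]["gene_terms"] = gene_thes.M

    # Stage 2: association mining ----------------------------------------
    vectors, matrix, pairs, relations = mine_stage(
        corpus, gene_thes, rel_thes, config.association_threshold, config.log_base
    )
    rel_best = {p: r.best_relation for p, r in relations.items()}
    assoc_df = association_table(matrix, relations)
    write_tsv(assoc_df, out / "association_table.tsv")
    manifest["counts"]["nonzero_associations"] = int(
        (matrix.scores > 0).sum() // 2
    )
    manifest["counts"]["retained_associations"] = len(pairs)
    manifest["decisions"]["association_threshold_value"] = matrix.threshold

    # Stage 3: GO + structure validation ----------------------------------
    stage = "3-validation"
    annot_path = _require(config.annotations, "GO annotations", stage)
    annots = (
        read_gaf(annot_path)
        if annot_path.suffix.lower() == ".gaf"
        else read_annotations_tsv(annot_path)
    )
    tf_terms = read_id_list(_require(config.tf_terms, "TF term list", stage))
    sims, flags = go_stage(annots, tf_terms, pairs)
    write_tsv(distance_table(sims.values()), out / "go_distances.tsv")
    write_tsv(
        pd.DataFrame(
            [
                {
                    "protein": pid,
                    "is_tf": f.is_tf,
                    "matched_functionalities": ";".join(sorted(f.matched_functionalities)),
                }
                for pid, f in sorted(flags.items())
            ]
        ),
        out / "tf_flags.tsv",
    )
    go_valid = {p for p, s in sims.items() if not s.undefined and s.distance_overall < 1.0}
    manifest["counts"]["go_validated_edges"] = len(go_valid)

    calls: dict = {}
    if config.structures_dir and config.structure_map:
        map_rows = read_structure_map(_require(config.structure_map, "structure map", stage))
        _require(config.structures_dir, "structures directory", stage)
        struct_df, calls = structure_stage(
            map_rows, config.structures_dir, pairs,
            config.distance_threshold, config.min_residue_fraction,
            config.structure_fraction_threshold,
        )
        write_tsv(struct_df, out / "structure_pairs.tsv")
        from .structure_interaction import call_table

        write_tsv(call_table(sorted(calls.values(), key=lambda c: c.pair)),
                  out / "structure_calls.tsv")
    manifest["counts"]["structurally_scored_edges"] = len(
        [p for p in calls if p in go_valid]
    )

    # Stage 4: network construction ---------------------------------------
    g = build_network(
        pairs, sims, calls, flags, rel_best,
        {p: matrix.score(*p) for p in pairs},
    )
    g = compute_topology(g)
    colon = read_id_list(config.colon_list) if config.colon_list else []
    cancer = read_id_list(config.cancer_list) if config.cancer_list else []
    other = read_id_list(config.other_list) if config.other_list else []
    g = tier_evidence(g, colon, cancer, other)
    manifest["counts"]["network_nodes"] = g.number_of_nodes()
    manifest["counts"]["network_edges"] = g.number_of_edges()
    manifest["counts"]["network_tfs"] = sum(
        1 for n in g.nodes if g.nodes[n].get("is_tf")
    )
    write_graphml(g, out / "network.graphml")
    write_tsv(node_table(g), out / "node_table.tsv")
    write_tsv(edge_table(g), out / "edge_table.tsv")

    # Stage 5: prioritization and modules ---------------------------------
    pconfig = PrioritizationConfig(scheme=config.scheme, alpha=config.alpha_association)
    g = compute_node_features(g)
    ranking, assoc = rank_nodes(g, pconfig)
    write_tsv(ranking, out / "node_ranking.tsv")
    write_tsv(assoc, out / "tf_associations.tsv")
    manifest["counts"]["tf_associations"] = len(assoc)
    manifest["counts"]["significant_tf_associations"] = (
        int(assoc["significant"].sum()) if len(assoc) else 0
    )
    modules = extract_modules(
        g, ranking, config.module_size_cap, config.module_tf_fraction
    )
    scores = {m.module_id: score_module(m, ranking) for m in modules}
    sigs = module_significance(g, modules, config.module_binding)
    module_df = pd.DataFrame(
        [
            {
                "module_id": m.module_id,
                "anchor_tf": m.anchor_tf,
                "size": m.size,
                "members": ";".join(sorted(m.nodes)),
                "score": scores[m.module_id],
                "p_value": sigs[m.module_id].p_value,
                "binding": sigs[m.module_id].binding,
            }
            for m in modules
        ],
        columns=["module_id", "anchor_tf", "size", "members", "score", "p_value", "binding"],
    )
    write_tsv(module_df, out / "modules.tsv")
    write_tsv(size_summary(modules), out / "module_size_summary.tsv")
    ranked_modules = rank_modules(modules, scores, sigs, config.alpha_module)
    write_tsv(ranked_modules, out / "module_ranking.tsv")
    manifest["counts"]["modules"] = len(modules)
    manifest["counts"]["significant_modules"] = len(ranked_modules)

    # Stage 6: pathway enrichment -----------------------------------------
    stage = "6-enrichment"
    gmt = _require(config.pathways_gmt, "pathway GMT", stage)
    db = PathwayDB.from_gmt(gmt, config.pathway_groups)
    background_nodes = [n for n in g.nodes if n in db.background]
    if not background_nodes:
        raise DataError(f"stage {stage}: no network proteins found in the background")
    enrich = enrich_pathways(background_nodes, db, config.alpha_pathway)
    groups = classify_functional_groups(enrich)
    write_tsv(enrich, out / "enrichment.tsv")
    write_tsv(groups, out / "functional_groups.tsv")
    manifest["counts"]["pathways"] = len(db.pathways)
    manifest["counts"]["significant_pathways"] = int(enrich["significant"].sum())
    manifest["counts"]["functional_groups"] = len(groups)

    _check_manifest(manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _versions() -> dict[str, str]:
    import networkx
    import numpy
    import pandas
    import scipy

    return {
        "tfnetminer": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }


def _check_manifest(manifest: dict) -> None:
    c = manifest["counts"]
    if not (
        c["structurally_scored_edges"]
        <= c["go_validated_edges"]
        <= c["retained_associations"]
    ):
        raise DataError(
            "manifest invariant violated: structurally scored "
            f"({c['structurally_scored_edges']}) <= GO-validated "
            f"({c['go_validated_edges']}) <= retained "
            f"({c['retained_associations']})"
        )
    if any(v < 0 for v in c.values()):
        raise DataError("negative count in manifest")
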