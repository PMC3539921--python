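"""Deterministic synthetic fixtures with planted signal for every stage.

The generators emulate the pipeline's inputs — an abstract corpus with a gene
and a relation thesaurus, GO annotations, dimer structures, pathway gene
sets, and evidence-tier membership lists — with known ground truth planted
into each: gene pairs co-mentioned at a controlled rate (against
never-co-mentioned decoys of equal marginal frequency), annotation sets with
a controlled shared fraction, chain dimers with a geometric interface below
the contact threshold (against rigidly displaced decoys), and one pathway
enriched by construction. Every generator is a pure function of
(config, seed): each draws from its own pseudo-random stream derived from
the master seed by a stable label, so adding a generator never perturbs the
others, and identical configs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .annotation_similarity import ASPECTS, GOAnnotationSet
from .corpus_mining import Document, GeneThesaurus, RelationThesaurus
from .errors import ConfigError

__all__ = [
    "FixtureConfig",
    "TruthTable",
    "generate_corpus",
    "generate_annotations",
    "generate_structures",
    "generate_pathways",
    "generate_membership_lists",
    "generate_all",
    "generate_scored_network",
    "generate_module_network",
    "DEFAULT_TF_GO_TERMS",
]

#: Stand-ins for the six TF-functionality GO terms (TF activity, activator,
#: co-activator, repressor, co-repressor, DNA-binding transcription
#: activity). Synthetic identifiers; real runs supply curated GO ids.
DEFAULT_TF_GO_TERMS = tuple(f"GO:TF{i:05d}" for i in range(1, 7))

_RELATIONS = {
    "activation": ("activates", "induces", "upregulates"),
    "binding": ("binds", "interacts"),
    "inhibition": ("inhibits", "represses", "downregulates"),
}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic fixture set."""

    seed: int = 0
    n_genes: int = 40
    n_tfs: int = 5
    n_docs: int = 100
    comention_rate: float = 0.12
    background_mention_rate: float = 0.03
    n_decoy_pairs: int = 2
    go_private_terms: int = 3
    go_shared_terms: int = 3
    n_residues: int = 30
    interface_distance: float = 5.0
    decoy_offset: float = 50.0
    structures_per_pair: int = 3
    structure_decoys_per_pair: int = 1
    structure_pair_fraction: float = 0.5
    n_pathways: int = 12
    pathway_size_min: int = 8
    pathway_size_max: int = 25
    n_background_genes: int = 300
    planted_enrichment: bool = True
    tf_go_terms: tuple[str, ...] = DEFAULT_TF_GO_TERMS

    def __post_init__(self) -> None:
        for name in ("comention_rate", "background_mention_rate",
                     "structure_pair_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_tfs > self.n_genes:
            raise ConfigError("n_tfs exceeds n_genes")

    @property
    def genes(self) -> list[str]:
        return [f"G{i:03d}" for i in range(1, self.n_genes + 1)]

    @property
    def tf_ids(self) -> list[str]:
        return self.genes[: self.n_tfs]

    @property
    def hub_id(self) -> str:
        return self.genes[0]

    @property
    def planted_pairs(self) -> list[tuple[str, str]]:
        """Planted associations: a TF triangle around the hub plus TF–non-TF
        spokes (8 pairs under the defaults).

        Each gene participates in at most two pairs so its document frequency
        stays in the idf-informative regime; a gene mentioned in most
        documents would have its tf*idf weight collapse toward zero.
        """
        g = self.genes
        pairs = [
            (g[0], g[1]), (g[0], g[2]), (g[1], g[2]),  # TF triangle w/ hub
            (g[3], g[5]), (g[3], g[6]),
            (g[4], g[7]), (g[4], g[8]),
            (g[5], g[7]),
            (g[9], g[10]), (g[11], g[12]), (g[13], g[14]),
        ]
        return [tuple(sorted(p)) for p in pairs if p[0] != p[1]][: 11]

    @property
    def decoy_pairs(self) -> list[tuple[str, str]]:
        g = self.genes
        base = self.n_genes - 2 * self.n_decoy_pairs
        return [
            (g[base + 2 * i], g[base + 2 * i + 1])
            for i in range(self.n_decoy_pairs)
        ]


@dataclass
class TruthTable:
    """Ground truth planted into the generated fixture set."""

    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    comention_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    pair_relations: dict[tuple[str, str], str] = field(default_factory=dict)
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)
    tf_ids: list[str] = field(default_factory=list)
    hub_id: str = ""
    structural_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_pathway: str | None = None
    user_genes: list[str] = field(default_factory=list)


def _rng(seed: int, label: str) -> np.random.Generator:
    """Per-generator stream: master seed plus a stable label hash."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def _planted_genes(config: FixtureConfig) -> set[str]:
    out = set(config.tf_ids)
    for a, b in config.planted_pairs:
        out |= {a, b}
    return out


def generate_corpus(
    config: FixtureConfig,
) -> tuple[list[Document], GeneThesaurus, RelationThesaurus, TruthTable]:
    """Generate abstracts with planted co-mentions and matched decoys.

    Each planted pair is co-mentioned, with a relation trigger, in exactly
    round(comention_rate · n_docs) documents. Each decoy-pair gene is
    mentioned alone in the same number of documents, split between even and
    odd document indices so the decoy partners never share a document.
    Remaining genes appear independently at the background rate.
    """
    rng = _rng(config.seed, "corpus")
    truth = TruthTable(
        planted_pairs=list(config.planted_pairs),
        decoy_pairs=list(config.decoy_pairs),
        tf_ids=list(config.tf_ids),
        hub_id=config.hub_id,
    )
    relation_labels = sorted(_RELATIONS)
    sentences: dict[int, list[str]] = {i: [] for i in range(config.n_docs)}
    n_co = int(round(config.comention_rate * config.n_docs))

    syn = {g: (g, f"{g.lower()}p") for g in config.genes}
    for idx, (a, b) in enumerate(config.planted_pairs):
        label = relation_labels[idx % len(relation_labels)]
        trigger = _RELATIONS[label][idx % len(_RELATIONS[label])]
        docs = rng.choice(config.n_docs, size=n_co, replace=False)
        for d in docs:
            sentences[int(d)].append(f"{syn[a][0]} {trigger} {syn[b][0]} in colon tissue.")
        truth.comention_counts[(a, b)] = n_co
        truth.pair_relations[(a, b)] = label

    decoy_genes = {g for p in config.decoy_pairs for g in p}
    for a, b in config.decoy_pairs:
        evens = [i for i in range(config.n_docs) if i % 2 == 0]
        odds = [i for i in range(config.n_docs) if i % 2 == 1]
        for gene, pool in ((a, evens), (b, odds)):
            docs = rng.choice(len(pool), size=min(n_co, len(pool)), replace=False)
            for d in docs:
                sentences[pool[int(d)]].append(f"{syn[gene][1]} was detected in tumours.")

    special = _planted_genes(config) | decoy_genes
    for gene in config.genes:
        if gene in special:
            continue
        n_mention = rng.binomial(config.n_docs, config.background_mention_rate)
        if n_mention == 0:
            continue
        docs = rng.choice(config.n_docs, size=n_mention, replace=False)
        for d in docs:
            sentences[int(d)].append(f"{syn[gene][0]} expression was examined.")

    docs_out = []
    for i in range(config.n_docs):
        body = ["Colorectal cancer progression was studied."] + sentences[i]
        docs_out.append(Document(f"D{i:04d}", " ".join(body)))
    gene_thes = GeneThesaurus({g: set(syn[g]) for g in config.genes})
    rel_thes = RelationThesaurus({k: set(v) for k, v in _RELATIONS.items()})
    return docs_out, gene_thes, rel_thes, truth


def generate_annotations(config: FixtureConfig) -> dict[str, GOAnnotationSet]:
    """GO annotations: private terms per protein, shared terms per planted
    pair (so planted pairs have Czekanowski-Dice distance < 1), and one
    TF-functionality term per TF."""
    terms: dict[str, set[str]] = {g: set() for g in config.genes}
    aspect_of: dict[str, dict[str, str]] = {g: {} for g in config.genes}
    for g in config.genes:
        for j in range(config.go_private_terms):
            t = f"GO:P{g[1:]}{j:02d}"
            terms[g].add(t)
            aspect_of[g][t] = ASPECTS[j % len(ASPECTS)]
    for idx, (a, b) in enumerate(config.planted_pairs):
        for j in range(config.go_shared_terms):
            t = f"GO:S{idx:03d}{j:02d}"
            for g in (a, b):
                terms[g].add(t)
                aspect_of[g][t] = ASPECTS[j % len(ASPECTS)]
    for i, tf in enumerate(config.tf_ids):
        t = config.tf_go_terms[i % len(config.tf_go_terms)]
        terms[tf].add(t)
        aspect_of[tf][t] = "MF"
    return {
        g: GOAnnotationSet(g, frozenset(terms[g]), dict(aspect_of[g]))
        for g in config.genes
    }


def _helix(n: int, seed_stream: np.random.Generator | None = None) -> np.ndarray:
    """C-alpha trace on an ideal alpha-helical template (rise 1.5 Å,
    radius 2.3 Å, 100° per residue)."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )


_RESTYPES = ("LEU", "ILE", "VAL", "PHE", "ALA", "MET", "SER", "LYS", "GLU", "THR")


def _write_dimer(
    path: Path, coords_a: np.ndarray, coords_b: np.ndarray, name: str
) -> None:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for cname, coords in (("A", coords_a), ("B", coords_b)):
        chain = gemmi.Chain(cname)
        for i, (x, y, z) in enumerate(coords):
            res = gemmi.Residue()
            res.name = _RESTYPES[i % len(_RESTYPES)]
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def generate_structures(
    config: FixtureConfig, out_dir: str | Path
) -> tuple[list[tuple[str, str, str]], TruthTable]:
    """Write dimer PDB files and the protein→structure mapping TSV.

    A fraction of the planted pairs receives structures: per pair,
    ``structures_per_pair`` entries of which ``structure_decoys_per_pair``
    are decoys with chain B rigidly displaced by ``decoy_offset`` Å. In
    contact entries, chain B is the chain-A helix offset laterally by
    ``interface_distance``, so every residue has a partner C-alpha within
    the contact threshold.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, "structures")
    n_struct_pairs = int(round(len(config.planted_pairs) * config.structure_pair_fraction))
    chosen = config.planted_pairs[:n_struct_pairs]
    mapping: list[tuple[str, str, str]] = []
    truth = TruthTable(structural_pairs=[tuple(p) for p in chosen])
    for pi, (a, b) in enumerate(chosen):
        base = _helix(config.n_residues)
        base = base + rng.normal(0.0, 0.05, size=base.shape)  # crystal jitter
        for si in range(config.structures_per_pair):
            decoy = si >= config.structures_per_pair - config.structure_decoys_per_pair
            offset = config.decoy_offset if decoy else config.interface_distance
            coords_b = base + np.array([offset, 0.0, 0.0])
            pdb_id = f"SYN{pi:02d}{si}"
            _write_dimer(out_dir / f"{pdb_id.lower()}.pdb", base, coords_b, pdb_id)
            mapping.append((a, pdb_id, "A"))
            mapping.append((b, pdb_id, "B"))
    return mapping, truth


def generate_pathways(
    config: FixtureConfig,
) -> tuple[dict[str, frozenset[str]], dict[str, str], TruthTable]:
    """Pathway gene sets over a padded background, with one pathway enriched
    by construction when ``planted_enrichment`` is set (its overlap with the
    planted user list is far beyond chance for the default geometry)."""
    rng = _rng(config.seed, "pathways")
    user = sorted(_planted_genes(config))
    if not user:
        raise ConfigError("no planted user genes; cannot plant enrichment")
    background = list(config.genes) + [
        f"BKG{i:03d}" for i in range(config.n_background_genes - config.n_genes)
    ]
    groups = ["Apoptosis", "Cell cycle", "Signal transduction", "Adhesion"]
    pathways: dict[str, frozenset[str]] = {}
    group_of: dict[str, str] = {}
    truth = TruthTable(user_genes=user)
    start = 0
    if config.planted_enrichment:
        n_overlap = min(10, len(user))
        fill = [g for g in background if g not in user]
        picked = list(rng.choice(len(fill), size=5, replace=False))
        genes = set(user[:n_overlap]) | {fill[int(i)] for i in picked}
        pathways["PW000"] = frozenset(genes)
        group_of["PW000"] = groups[0]
        truth.planted_pathway = "PW000"
        start = 1
    for i in range(start, config.n_pathways):
        size = int(rng.integers(config.pathway_size_min, config.pathway_size_max + 1))
        idx = rng.choice(len(background), size=size, replace=False)
        pid = f"PW{i:03d}"
        pathways[pid] = frozenset(background[int(j)] for j in idx)
        group_of[pid] = groups[i % len(groups)]
    return pathways, group_of, truth


def generate_membership_lists(config: FixtureConfig) -> dict[str, list[str]]:
    """Evidence-tier membership lists: disease-specific (colon), generic
    cancer/signalling, and other-pathway ids."""
    planted = sorted(_planted_genes(config))
    third = max(1, len(planted) // 3)
    return {
        "colon": planted[:third],
        "cancer": planted[third: 2 * third],
        "other": planted[2 * third:],
    }


def _merge_truth(dest: TruthTable, src: TruthTable) -> None:
    for f in dataclasses.fields(TruthTable):
        v = getattr(src, f.name)
        if v:
            setattr(dest, f.name, v)


def generate_all(config: FixtureConfig, out_dir: str | Path) -> TruthTable:
    """Write the complete fixture set and its truth tables to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs, gene_thes, rel_thes, truth = generate_corpus(config)
    with open(out / "corpus.jsonl", "w") as fh:
        for d in docs:
            fh.write(json.dumps({"id": d.doc_id, "text": d.text}) + "\n")
    with open(out / "gene_thesaurus.tsv", "w") as fh:
        for cid in sorted(gene_thes.entries):
            for s in sorted(gene_thes.entries[cid]):
                fh.write(f"{cid}\t{s}\n")
    with open(out / "relation_thesaurus.tsv", "w") as fh:
        for label in sorted(rel_thes.entries):
            for t in sorted(rel_thes.entries[label]):
                fh.write(f"{label}\t{t}\n")

    annots = generate_annotations(config)
    with open(out / "annotations.tsv", "w") as fh:
        for pid in sorted(annots):
            a = annots[pid]
            for t in sorted(a.terms):
                fh.write(f"{pid}\t{t}\t{a.aspect_of[t]}\n")
    with open(out / "tf_terms.txt", "w") as fh:
        for t in config.tf_go_terms:
            fh.write(t + "\n")

    mapping, struct_truth = generate_structures(config, out / "structures")
    _merge_truth(truth, struct_truth)
    with open(out / "structure_map.tsv", "w") as fh:
        for prot, pdb_id, chain in mapping:
            fh.write(f"{prot}\t{pdb_id}\t{chain}\n")

    pathways, group_of, pw_truth = generate_pathways(config)
    _merge_truth(truth, pw_truth)
    with open(out / "pathways.gmt", "w") as fh:
        for pid in sorted(pathways):
            genes = "\t".join(sorted(pathways[pid]))
            fh.write(f"{pid}\tsynthetic pathway\t{genes}\n")
    with open(out / "pathway_groups.tsv", "w") as fh:
        for pid in sorted(group_of):
            fh.write(f"{pid}\t{group_of[pid]}\n")

    lists = generate_membership_lists(config)
    for name, ids in lists.items():
        with open(out / f"{name}_list.txt", "w") as fh:
            for g in ids:
                fh.write(g + "\n")

    pd.DataFrame(
        [
            {
                "gene_a": a, "gene_b": b,
                "comention_count": truth.comention_counts.get((a, b), 0),
                "relation": truth.pair_relations.get((a, b), ""),
            }
            for a, b in truth.planted_pairs
        ]
    ).to_csv(out / "truth_associations.tsv", sep="\t", index=False)
    pd.DataFrame({"tf": truth.tf_ids}).to_csv(
        out / "truth_tfs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"gene_a": a, "gene_b": b} for a, b in truth.decoy_pairs]
    ).to_csv(out / "truth_decoys.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "item": "hub", "value": truth.hub_id,
            },
            {
                "item": "planted_pathway", "value": truth.planted_pathway or "",
            },
        ]
    ).to_csv(out / "truth_misc.tsv", sep="\t", index=False)
    with open(out / "fixture_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return truth


def generate_scored_network(
    seed: int, n_nodes: int = 40, n_tfs: int = 8, edge_prob: float = 0.15
) -> tuple[nx.Graph, str]:
    """Random network with fully annotated node features and one planted TF
    whose four features are all drawn from the top quartile.

    Used to exercise ranking recovery: background node features are uniform
    on [0, 1]; the planted TF's are uniform on [0.75, 1].
    """
    rng = _rng(seed, "scored-network")
    g = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
    nodes = sorted(g.nodes)
    tfs = [nodes[int(i)] for i in rng.choice(n_nodes, size=n_tfs, replace=False)]
    planted = tfs[0]
    for node in nodes:
        top = node == planted
        for feat in ("clustering", "betweenness_norm", "go_score", "propensity"):
            lo, hi = (0.75, 1.0) if top else (0.0, 1.0)
            g.nodes[node][feat] = float(rng.uniform(lo, hi))
        g.nodes[node]["is_tf"] = node in tfs
        g.nodes[node]["degree"] = g.degree(node)
    return g, planted


def generate_module_network(
    seed: int, n_nodes: int = 30, n_tfs: int = 6
) -> tuple[nx.Graph, frozenset[str]]:
    """Network with a planted TF triangle of top-strength nodes.

    The three planted TFs are mutually connected and carry feature values
    near 1; every other node's features stay at or below 0.6, so the planted
    size-3 module outscores any competitor containing a background node, and
    its all-TF content keeps it significant under the tf-content binding.
    """
    rng = _rng(seed, "module-network")
    g = nx.gnp_random_graph(n_nodes, 0.12, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
    nodes = sorted(g.nodes)
    planted = nodes[:3]
    g.add_edges_from([(planted[0], planted[1]), (planted[0], planted[2]),
                      (planted[1], planted[2])])
    tfs = set(planted) | {nodes[int(i)] for i in
                          rng.choice(range(3, n_nodes), size=n_tfs - 3, replace=False)}
    for node in nodes:
        top = node in planted
        for feat in ("clustering", "betweenness_norm", "go_score", "propensity"):
            lo, hi = (0.9, 1.0) if top else (0.0, 0.6)
            g.nodes[node][feat] = float(rng.uniform(lo, hi))
        g.nodes[node]["is_tf"] = node in tfs
        g.nodes[node]["degree"] = g.degree(node)
    return g, frozenset(planted)
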