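# Methods

`tfnetminer` builds a disease-specific transcription-factor (TF) interaction
network from a literature corpus and ranks TFs and TF modules by combined
topological and biological evidence. This note documents the model, the
parameters that matter, the numerical choices made where the method
description was genuinely open, and what the synthetic fixtures do and do
not establish.

## 1. Association mining (corpus → candidate gene pairs)

Each abstract *d_i* is mapped to an M-dimensional vector over the gene
thesaurus with tf*idf weights

    W_ik = T_ik · log(N / n_k)

where `T_ik` is the raw in-document count of any synonym of term *k*
(binary counts are available via `binary_tf=True`), `N` the corpus size and
`n_k` the term's document frequency. The log base defaults to 10 and is
recorded in the run manifest; it rescales all weights uniformly, so it
cannot change pair rankings, only absolute score values.

The gene–gene association is the cross-document dot product
`Σ_i W_ik · W_il`. Pairs at or above a threshold are retained. The
threshold is user-defined; the default is the **95th percentile of the
non-zero scores**, a scale-free choice because absolute association values
grow with corpus size. Zero-score pairs are never retained, even at
threshold 0.

Dictionary matching is case-insensitive on token boundaries, longest
synonym first, resolved left-to-right — the standard deterministic
dictionary-NER compromise. Sentences are split on terminal punctuation
followed by whitespace and an uppercase letter or digit (configurable
regex). Relations are typed per retained pair by counting sentences that
contain synonyms of both genes plus a trigger word of a relation label;
the argmax label wins, with ties broken to the lexicographically smallest
label for reproducibility.

## 2. GO validation and TF flagging

Protein pairs are compared by the Czekanowski-Dice distance on their GO
annotation sets, d = |AΔB| / (|A∪B| + |A∩B|). A pair with d < 1.0 (any
shared annotation) is accepted as a GO-supported interaction; the
similarity 1 − d becomes the edge weight used in node scoring. Distances
are also reported per GO aspect (BP/MF/CC) because the aspects carry
independent signal. Two deliberate choices:

- Terms are compared **as annotated** — no DAG ancestor closure. Closure
  would only decrease distances; it is left as future work.
- When both annotation sets are empty the distance is **undefined** (NaN),
  not 0 or 1; undefined pairs are not interacting and are flagged.

TFs are flagged by intersecting a protein's annotations with a configured
term list covering the six TF functionalities (TF activity, activator,
co-activator, repressor, co-repressor, DNA-binding transcription
activity). The list is data, not code: GO identifiers for these concepts
depend on the ontology release, so fixtures ship synthetic stand-ins and
real runs supply curated IDs.

## 3. Structure-based interaction calls

For a protein pair with solved structures: probable interface residues are
predicted per chain; a predicted residue counts as *interacting* when its
C-alpha lies within **6 Å** of any predicted residue of the partner chain;
the structure-pair score is `interacting / probable` over the **union** of
both chains' predicted residues, satisfying at **≥ 10%**; the protein pair
is called interacting when **≥ 30%** of its structure pairs satisfy. All
three comparisons are inclusive. Pairs with no structures yield a distinct
"no structural evidence" outcome, never a negative call.

The interface predictor is pluggable. The default scores each residue as
an equal-weight combination of Kyte-Doolittle hydropathy (min-max scaled
to [0, 1]) and a centroid-distance exposure proxy (distance from the chain
centroid over the maximum such distance; 1.0 for a single-residue chain),
keeping residues scoring ≥ 0.5. It is deterministic, depends only on
coordinates and residue types, and is not a trained method; an
"all residues" predictor is provided for testing and for skipping the
physico-chemical screen.

Chains are compared **only within a shared PDB entry**: C-alpha distances
across different crystals are not expressed in a common frame, so
cross-entry pairing would compare meaningless coordinates. A pair's
structure set is therefore the set of entries that map both proteins.
Residues without a resolved C-alpha are skipped and counted in a coverage
statistic. The per-pair structural edge weight used downstream is the mean
of the defined structure-pair scores.

## 4. Network, topology, evidence tiers

Edges are the retained pairs with GO distance < 1.0; structural scores are
attached where available, and GO-only edges are kept (structure coverage is
always partial). The network is undirected with no self-loops.

Topology: degree; clustering coefficient C_i = 2n/(k_i(k_i−1)); betweenness
centrality, reported raw and normalized per connected component by
(n_c−1)(n_c−2)/2. The normalized form enters node scoring so that one
unbounded feature cannot dominate the [0, 1]-scaled features; the raw value
is reported alongside. Isolated nodes carry zeros.

Evidence tiers classify nodes by membership lists: disease-specific
pathway list → HIGH, generic cancer/signalling list → MEDIUM, any other
pathway list → LOW, none → UNKNOWN. Edge tiers: HIGH if either endpoint is
HIGH; MEDIUM if the best endpoint is MEDIUM; LOW only when both endpoints
are LOW. UNKNOWN endpoints behave as LOW but flag the edge — UNKNOWN is
this package's closure of a rule table that assumed every protein appears
in some list.

## 5. Node prioritization

Each node carries four features: clustering, normalized betweenness, GO
score (mean incident-edge GO similarity), and interaction propensity
(mean incident structural score over the network-wide mean — proteins
tend to interact within their own structural families, so above-average
structural support is informative). Edges without structural scores
contribute 0 to both means but stay in the counts as long as at least one
edge network-wide is scored; a fully unscored network yields propensity 0
everywhere, flagged.

Node strength:

- **unweighted**: arithmetic mean of the four features;
- **weighted** (default): `0.4·propensity + 0.2·(clustering + betweenness
  + GO score)`. The printed weighted formula this follows also lists
  propensity inside the 0.2 bracket, making the weights sum to 1.2 and
  counting the structural feature twice; the default renormalizes to sum
  1.0 while preserving the 2:1 structural emphasis, keeping weighted and
  unweighted strengths comparable. The literal form is available as
  `weighted_literal`, and the active scheme is recorded in every output.

Ties in the ranking break by node id. Node–node association: TF pairs in
the same connected component are scored by the hypergeometric point
probability of their shared-neighbor count m given neighbor counts n1, n2
among N network proteins; **small p = significant** (the method's own
description once states the opposite, but its result tables rank
p ≈ 1E-63 on top, and standard usage agrees). N is the network protein
count, not the full mined-entity count. Raw p-values are filtered at
α = 0.05 without multiple-testing correction, mirroring the original
analysis; Benjamini-Hochberg q-values are emitted as an extra column.

All hypergeometric masses and tails in the package are computed in
log-factorial space (log-gamma plus log-sum-exp), exact at small sizes and
stable at backgrounds of 10⁴⁺.

## 6. Modules

A module is a connected induced subgraph (size 3 up to a cap, default 8)
of a prioritized TF's ego network that contains the TF. Prioritized TFs
are the top 50% of TFs by the active ranking (configurable). Enumeration
is exhaustive within each ego network with node-set deduplication across
anchors and a per-TF guard (default 10⁵ subgraphs, truncation logged).
Module score = mean member node strength; ranking is score-descending
within each size class, restricted to modules whose significance passes
p < 0.05.

The module significance formula's symbol list is internally inconsistent
(its "S" counts modules but is paired with node totals; its "k" is called
"the module"). The implementation therefore computes the generic
1 − CDF(k−1) hypergeometric tail under a **named, recorded binding**:

- `literal` — population = N nodes, successes = S modules excluding the
  TF, draws = C, threshold k: the symbols exactly as listed. This is the
  operation's default, but it is infeasible whenever S > N, which happens
  on any realistically enumerated network (module counts routinely exceed
  node counts).
- `modules` — population = all modules, successes = modules containing
  the TF.
- `tf-content` — population = N nodes, successes = TF nodes, draws = C,
  k = TFs observed in the module: does the module contain more TFs than
  chance? Always feasible; this is the **pipeline default**, and every
  output row names its binding.

## 7. Pathway enrichment

For a protein list of size R against a pathway with n genes in a
background of N genes, with overlap r, the p-value is the upper
hypergeometric tail P(X ≥ r). The background defaults to the union of all
GMT genes (self-contained and conventional) and is overridable — the
original analysis used a licensed commercial database as background, which
is data this package does not assume. Pathways with p < α (default 0.05)
are significant; functional groups with more than 3 significant pathways
are "major", others "minor"; groups are supplied as an optional
pathway→group TSV.

## 8. Synthetic fixtures: what they emulate and what they do not

The fixture generators are pure functions of (config, seed); each draws
from a stream derived from the master seed by a stable label, so adding a
generator never perturbs the others, and identical configs are
byte-identical on disk.

Default study conditions (chosen once, as a realistic desk-scale corpus;
full-scale literature mining is out of scope): 40 genes, 5 TFs, 100
abstracts. Eleven planted pairs — a TF triangle around the hub plus
TF–gene and gene–gene spokes — are co-mentioned with a relation trigger in
exactly 12% of documents each; background genes are mentioned
independently at 3%. Each planted gene sits in at most two pairs so its
document frequency stays in the idf-informative regime: a gene mentioned
in most documents has its tf*idf weight, and hence all its associations,
collapse toward zero — with these rates the planted pairs are the
top-scoring associations by a wide margin, which is the generator's
contract. Decoy pairs are mentioned at matched rates but split across
even/odd documents so they never co-occur (association exactly 0).

Annotations give each protein three private GO terms, each planted pair
three shared terms (distance strictly below 1), and each TF one term from
the configured TF list. Structures are C-alpha helices (rise 1.5 Å,
radius 2.3 Å, 100°/residue) written as two-chain PDB entries: contact
entries offset chain B laterally by 5 Å, decoy entries by 50 Å; half of
the planted pairs receive 3 entries each (1 decoy), mirroring partial
structural coverage. Pathways span a 300-gene background with one pathway
built to overlap the planted genes (tail p ≪ 0.01 by construction) and
the rest drawn uniformly.

What passing on these fixtures shows: the algebra, thresholds and rules
are implemented correctly; planted signal of realistic geometry survives
every stage; p-values are calibrated under the null. What it does not
show: robustness to real biomedical text (ambiguous names,
abbreviations), to incomplete or biased GO annotation, or to real protein
folds — the helical chains exercise geometry thresholds, not structural
realism, and the corpus is template text, not language.

Two auxiliary generators support recovery studies at the network level:
`generate_scored_network` (40 nodes; one TF's four features drawn from the
top quartile, uniform elsewhere) and `generate_module_network` (a planted
triangle of three top-strength TFs among weaker background nodes).

## 9. Numerical and formatting conventions

Hypergeometric tails short-circuit to exactly 1.0 (whole support) and 0.0
(beyond support) to avoid round-off at the boundaries. TSV outputs are
UTF-8 with LF endings, floats at 6 significant digits, p-values in
scientific notation; tables carry stable column orders, and sorts use a
stable algorithm with explicit id tie-breaks, so identical runs are
byte-identical. The manifest records config (minus the output directory),
library versions, per-stage counts, and every resolved methodological
choice; it enforces structurally scored ≤ GO-validated ≤ retained.

## 10. Known limitations

- Dictionary NER only: no abbreviation disambiguation or species
  resolution; thesaurus quality bounds mining quality.
- GO distance treats annotations as flat sets; shallow vs deep annotation
  depth is not corrected for.
- The default interface predictor is a deliberate simple screen, not a
  validated method; supply a custom predictor for serious structural work.
- Module enumeration is exponential in ego-network size; the cap and
  guard bound compute at the cost of completeness on dense hubs
  (truncation is logged).
- The problem sizes used by the test suite and the acceptance script
  (desk-scale corpora, seed sweeps of 20–200) are the package's own
  choices for a self-contained, deterministic evaluation.
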