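"""Corpus mining: tf*idf weights, association matrix, thresholding, typed
relations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import association_matrix_bruteforce
from tfnetminer.corpus_mining import (
    Document,
    GeneThesaurus,
    RelationThesaurus,
    build_term_vectors,
    compute_association_matrix,
    extract_relations,
    threshold_associations,
)
from tfnetminer.errors import ConfigError, DataError, ThesaurusError
from tfnetminer.synthetic_fixtures import FixtureConfig, generate_corpus


@pytest.fixture
def thesaurus():
    return GeneThesaurus({"GA": {"GENEA", "gea1"}, "GB": {"GENEB"}, "GC": {"GENEC"}})


def _corpus(texts):
    return [Document(f"d{i}", t) for i, t in enumerate(texts)]


class TestTermVectors:
    def test_weight_formula_single_doc_occurrence(self, thesaurus):
        """Term occurring twice in one of four documents: W = 2·log10(4)."""
        corpus = _corpus(
            ["GENEA and GENEA again.", "GENEB here.", "GENEB also.", "GENEB too."]
        )
        vs = build_term_vectors(corpus, thesaurus, log_base=10)
        k = vs.terms.index("GA")
        assert vs.term_freq[0, k] == 2
        assert vs.weights[0, k] == pytest.approx(2 * math.log10(4), abs=1e-12)

    def test_ubiquitous_term_weighs_zero(self, thesaurus):
        corpus = _corpus(["GENEA one.", "GENEA GENEA two.", "gea1 three."])
        vs = build_term_vectors(corpus, thesaurus)
        k = vs.terms.index("GA")
        assert np.all(vs.weights[:, k] == 0.0)  # n_k = N

    def test_absent_term_weighs_zero(self, thesaurus):
        vs = build_term_vectors(_corpus(["GENEA only."]), thesaurus)
        assert np.all(vs.weights[:, vs.terms.index("GB")] == 0.0)

    def test_synonyms_case_insensitive_token_bounded(self, thesaurus):
        vs = build_term_vectors(
            _corpus(["genea and GEA1 but not GENEAX."]), thesaurus
        )
        assert vs.term_freq[0, vs.terms.index("GA")] == 2

    def test_empty_corpus_raises(self, thesaurus):
        with pytest.raises(DataError):
            build_term_vectors([], thesaurus)

    def test_bad_log_base_raises(self, thesaurus):
        with pytest.raises(ConfigError):
            build_term_vectors(_corpus(["GENEA."]), thesaurus, log_base=1.0)

    def test_synonym_collision_is_load_error(self):
        with pytest.raises(ThesaurusError):
            GeneThesaurus({"GA": {"shared"}, "GB": {"SHARED"}})


class TestAssociationMatrix:
    def test_dot_product_example(self):
        """Weight columns (1.2, 0) and (0.6, 0.9) → association 0.72."""
        from tfnetminer.corpus_mining import AssociationMatrix, TermVectorSet

        vs = TermVectorSet(
            terms=["k", "l"],
            doc_ids=["a", "b"],
            term_freq=np.ones((2, 2)),
            doc_freq=np.array([1, 2]),
            weights=np.array([[1.2, 0.6], [0.0, 0.9]]),
            log_base=10,
        )
        mat = compute_association_matrix(vs)
        assert mat.score("k", "l") == pytest.approx(0.72)
        assert np.all(np.diag(mat.scores) == 0)

    def test_matches_bruteforce_double_loop(self, thesaurus):
        rng = np.random.default_rng(5)
        genes = ["GENEA", "GENEB", "GENEC"]
        for _ in range(10):
            texts = [
                " ".join(rng.choice(genes, size=rng.integers(0, 6))) + "."
                for _ in range(8)
            ]
            vs = build_term_vectors(_corpus(texts), thesaurus)
            mat = compute_association_matrix(vs)
            brute = association_matrix_bruteforce(vs.weights)
            assert np.allclose(mat.scores, brute, atol=1e-12)
            assert np.allclose(mat.scores, mat.scores.T)

    def test_term_free_document_content_is_irrelevant(self, thesaurus):
        """With N and every doc-frequency held fixed, the content of a
        document mentioning neither term of a pair cannot move any
        association: swapping it for different term-free text leaves the
        matrix exactly unchanged. (Appending a document instead changes N
        and hence every idf, so associations shift globally.)"""
        base = ["GENEA GENEB.", "GENEA here.", "GENEB there."]
        m1 = compute_association_matrix(
            build_term_vectors(_corpus(base + ["Nothing relevant at all."]), thesaurus)
        )
        m2 = compute_association_matrix(
            build_term_vectors(_corpus(base + ["Entirely different filler text."]), thesaurus)
        )
        assert np.array_equal(m1.scores, m2.scores)


class TestThreshold:
    def _matrix(self, thesaurus):
        corpus = _corpus(["GENEA GENEB.", "GENEA GENEC here.", "GENEB alone."])
        return compute_association_matrix(build_term_vectors(corpus, thesaurus))

    def test_exact_cutoff(self, thesaurus):
        mat = self._matrix(thesaurus)
        scores = sorted(
            mat.scores[np.triu_indices(3, 1)][mat.scores[np.triu_indices(3, 1)] > 0]
        )
        mid = (scores[0] + scores[-1]) / 2 if len(scores) > 1 else scores[0]
        pairs = threshold_associations(mat, mid)
        assert all(mat.score(*p) >= mid for p in pairs)

    def test_zero_threshold_excludes_zero_scores(self, thesaurus):
        mat = self._matrix(thesaurus)
        pairs = threshold_associations(mat, 0.0)
        assert all(mat.score(*p) > 0 for p in pairs)

    def test_above_max_empty(self, thesaurus):
        mat = self._matrix(thesaurus)
        assert threshold_associations(mat, mat.scores.max() + 1) == set()

    def test_negative_threshold_rejected(self, thesaurus):
        with pytest.raises(ConfigError):
            threshold_associations(self._matrix(thesaurus), -0.1)

    @given(st.floats(0, 5), st.floats(0, 5))
    def test_monotone_in_threshold(self, t1, t2):
        """Raising the threshold never adds pairs."""
        thes = GeneThesaurus({"GA": {"GENEA"}, "GB": {"GENEB"}, "GC": {"GENEC"}})
        corpus = _corpus(["GENEA GENEB.", "GENEA GENEC.", "GENEB GENEC.", "GENEA."])
        mat = compute_association_matrix(build_term_vectors(corpus, thes))
        lo, hi = sorted((t1, t2))
        assert threshold_associations(mat, hi) <= threshold_associations(mat, lo)


class TestRelations:
    @pytest.fixture
    def relations(self):
        return RelationThesaurus(
            {"activation": {"activates"}, "inhibition": {"inhibits", "represses"}}
        )

    def test_single_sentence_relation(self, thesaurus, relations):
        corpus = _corpus(["GENEA activates GENEB. Unrelated sentence follows."])
        res = extract_relations(corpus, ("GA", "GB"), thesaurus, relations)
        assert res.per_relation_score == {"activation": 1, "inhibition": 0}
        assert res.best_relation == "activation"

    def test_no_co_mention_gives_none(self, thesaurus, relations):
        corpus = _corpus(["GENEA activates GENEC.", "GENEB alone."])
        res = extract_relations(corpus, ("GA", "GB"), thesaurus, relations)
        assert res.best_relation is None
        assert all(v == 0 for v in res.per_relation_score.values())

    def test_majority_relation_wins(self, thesaurus, relations):
        corpus = _corpus(
            [
                "GENEA inhibits GENEB. GENEA represses GENEB. GENEA inhibits GENEB again.",
                "GENEA activates GENEB.",
            ]
        )
        res = extract_relations(corpus, ("GA", "GB"), thesaurus, relations)
        assert res.per_relation_score["inhibition"] == 3
        assert res.best_relation == "inhibition"

    def test_tie_breaks_lexicographically(self, thesaurus, relations):
        corpus = _corpus(["GENEA activates GENEB. GENEA inhibits GENEB."])
        res = extract_relations(corpus, ("GA", "GB"), thesaurus, relations)
        assert res.best_relation == "activation"

    def test_invariant_to_sentence_order(self, thesaurus, relations):
        s = ["GENEA activates GENEB.", "GENEB represses GENEA.", "GENEC alone."]
        fwd = extract_relations(
            _corpus([" ".join(s)]), ("GA", "GB"), thesaurus, relations
        )
        rev = extract_relations(
            _corpus([" ".join(reversed(s))]), ("GA", "GB"), thesaurus, relations
        )
        assert fwd.per_relation_score == rev.per_relation_score

    def test_trigger_shared_across_labels_rejected(self):
        with pytest.raises(ThesaurusError):
            RelationThesaurus({"a": {"binds"}, "b": {"BINDS"}})


def test_planted_pair_beats_equal_marginal_decoy():
    """In every generated corpus, a planted co-mentioned pair scores strictly
    above a never-co-mentioned decoy pair of matched marginal frequency."""
    for seed in range(5):
        docs, gene_thes, _, truth = generate_corpus(FixtureConfig(seed=seed))
        vs = build_term_vectors(docs, gene_thes)
        mat = compute_association_matrix(vs)
        decoy_max = max(mat.score(*p) for p in truth.decoy_pairs)
        assert decoy_max == 0.0
        for pair in truth.planted_pairs:
            assert mat.score(*pair) > decoy_max
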