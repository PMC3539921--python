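"""Module enumeration vs exhaustive oracles, module scores, TF significance."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import connected_subgraphs_bruteforce, hypergeom_tail_exact
from tfnetminer.errors import ConfigError, DataError
from tfnetminer.module_analysis import (
    Module,
    enumerate_connected_subgraphs,
    extract_modules,
    module_significance,
    module_tf_pvalue,
    rank_modules,
    score_module,
    size_summary,
)
from tfnetminer.prioritization import PrioritizationConfig, rank_nodes
from tfnetminer.synthetic_fixtures import generate_module_network


def _ranking(strengths, tfs=()):
    rows = [
        {"node": n, "node_strength": s, "is_tf": n in tfs}
        for n, s in strengths.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["node_strength", "node"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df


class TestEnumeration:
    @pytest.mark.parametrize("trial", range(15))
    def test_matches_bruteforce_on_random_graphs(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 11))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)), seed=trial + 100)
        root = 0
        adj = {v: set(g[v]) for v in g.nodes}
        expected = connected_subgraphs_bruteforce(adj, root, 3, n)
        got = set(enumerate_connected_subgraphs(g, root, 3, n))
        assert got == expected

    def test_tf_with_two_neighbors_single_module(self):
        g = nx.Graph([("tf", "a"), ("tf", "b")])
        ranking = _ranking({"tf": 0.9, "a": 0.5, "b": 0.4}, tfs={"tf"})
        mods = extract_modules(g, ranking, size_cap=5, tf_fraction=1.0)
        assert [m.nodes for m in mods] == [frozenset({"tf", "a", "b"})]

    def test_isolated_tf_no_modules(self):
        g = nx.Graph()
        g.add_node("tf")
        ranking = _ranking({"tf": 0.9}, tfs={"tf"})
        assert extract_modules(g, ranking, size_cap=5, tf_fraction=1.0) == []

    def test_no_tfs_no_modules(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        ranking = _ranking({"a": 0.5, "b": 0.4, "c": 0.3})
        assert extract_modules(g, ranking, size_cap=5) == []

    def test_size_cap_below_three_rejected(self):
        with pytest.raises(ConfigError):
            extract_modules(nx.Graph(), _ranking({"a": 0.5}), size_cap=2)

    def test_emitted_modules_connected_and_anchored(self):
        g, _ = generate_module_network(7)
        ranking, _ = rank_nodes(g)
        for m in extract_modules(g, ranking, size_cap=5):
            assert 3 <= m.size <= 5
            assert m.anchor_tf in m.nodes
            assert nx.is_connected(g.subgraph(m.nodes))


class TestModuleScore:
    def test_mean_of_members(self):
        m = Module("M1", "tf", frozenset({"tf", "a", "b"}))
        ranking = _ranking({"tf": 0.2, "a": 0.4, "b": 0.6}, tfs={"tf"})
        assert score_module(m, ranking) == pytest.approx(0.4)

    def test_constant_strengths(self):
        m = Module("M1", "tf", frozenset({"tf", "a"}))
        ranking = _ranking({"tf": 0.4, "a": 0.4}, tfs={"tf"})
        assert score_module(m, ranking) == pytest.approx(0.4)

    def test_missing_member_is_error(self):
        m = Module("M1", "tf", frozenset({"tf", "ghost"}))
        with pytest.raises(DataError):
            score_module(m, _ranking({"tf": 0.4}, tfs={"tf"}))


class TestModulePvalue:
    def test_k_zero_is_one(self):
        assert module_tf_pvalue(10, 4, 5, 0) == 1.0

    def test_k_beyond_support_is_zero(self):
        assert module_tf_pvalue(10, 4, 5, 5) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        """Population 10, 4 marked, 5 drawn, threshold 1:
        1 − C(4,0)·C(6,5)/C(10,5) = 1 − 6/252."""
        assert module_tf_pvalue(10, 4, 5, 1) == pytest.approx(1 - 6 / 252)

    def test_matches_rational_oracle_on_small_grids(self):
        for population in range(1, 10):
            for successes in range(population + 1):
                for draws in range(population + 1):
                    for k in range(min(successes, draws) + 2):
                        exact = float(hypergeom_tail_exact(k, population, successes, draws))
                        assert module_tf_pvalue(population, successes, draws, k) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_non_increasing_in_k(self):
        for k in range(0, 6):
            assert module_tf_pvalue(12, 5, 6, k + 1) <= module_tf_pvalue(12, 5, 6, k) + 1e-12

    def test_infeasible_binding_raises(self):
        with pytest.raises(DataError):
            module_tf_pvalue(5, 9, 3, 1)  # successes exceed population


class TestSignificanceBindings:
    def test_bindings_recorded_and_feasible(self):
        g, _ = generate_module_network(1)
        ranking, _ = rank_nodes(g)
        mods = extract_modules(g, ranking, size_cap=4)
        sigs = module_significance(g, mods, "tf-content")
        assert all(s.binding == "tf-content" for s in sigs.values())
        assert all(0.0 <= s.p_value <= 1.0 for s in sigs.values())

    def test_unknown_binding_rejected(self):
        with pytest.raises(ConfigError):
            module_significance(nx.Graph(), [], "bogus")


class TestRankModules:
    def test_filter_and_ordering(self):
        mods = [
            Module("M1", "t", frozenset("abc")),
            Module("M2", "t", frozenset("abd")),
            Module("M3", "t", frozenset("abcd")),
        ]
        scores = {"M1": 0.5, "M2": 0.9, "M3": 0.7}
        from tfnetminer.module_analysis import ModuleSignificance

        sigs = {
            "M1": ModuleSignificance("t", "M1", 0.01, "literal", 9, 1, 3, 1),
            "M2": ModuleSignificance("t", "M2", 0.2, "literal", 9, 1, 3, 1),
            "M3": ModuleSignificance("t", "M3", 0.001, "literal", 9, 1, 4, 1),
        }
        ranked = rank_modules(mods, scores, sigs, alpha=0.05)
        assert list(ranked["module_id"]) == ["M1", "M3"]  # M2 filtered at α
        ranked_all = rank_modules(mods, scores, sigs, alpha=1.0)
        size3 = ranked_all[ranked_all["size"] == 3]
        assert list(size3["module_id"]) == ["M2", "M1"]  # score-descending

    def test_planted_module_tops_its_size_class(self):
        for seed in range(5):
            g, planted = generate_module_network(seed)
            ranking, _ = rank_nodes(g, PrioritizationConfig())
            mods = extract_modules(g, ranking, size_cap=6)
            scores = {m.module_id: score_module(m, ranking) for m in mods}
            sigs = module_significance(g, mods, "tf-content")
            ranked = rank_modules(mods, scores, sigs, 0.05)
            top3 = ranked[ranked["size"] == 3]
            assert len(top3)
            assert frozenset(top3.iloc[0]["members"].split(";")) == planted


def test_size_summary_counts():
    mods = [
        Module("M1", "t", frozenset("abc")),
        Module("M2", "t", frozenset("abd")),
        Module("M3", "t", frozenset("abde")),
    ]
    summary = size_summary(mods)
    assert dict(zip(summary["size"], summary["n_modules"])) == {3: 2, 4: 1}
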