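"""Structure-based interaction scores against brute-force distance oracles
and planted dimer/decoy geometry."""

import numpy as np
import pytest

from oracles import structure_score_bruteforce
from tfnetminer.structure_interaction import (
    AllResiduesPredictor,
    ChainStructure,
    HydrophobicityExposurePredictor,
    InterfacePrediction,
    Residue,
    pair_interaction_call,
    predict_interface_residues,
    read_chain,
    structure_pair_score,
)
from tfnetminer.errors import DataError
from tfnetminer.synthetic_fixtures import FixtureConfig, generate_structures


def _chain(sid, coords, restypes=None):
    coords = np.asarray(coords, dtype=float)
    restypes = restypes or ["ALA"] * len(coords)
    return ChainStructure(
        sid, sid, [Residue(i + 1, rt, tuple(c)) for i, (rt, c) in enumerate(zip(restypes, coords))]
    )


def _random_chain(rng, sid, n):
    return _chain(sid, rng.uniform(-20, 20, size=(n, 3)))


class TestPredictor:
    def test_empty_chain_empty_prediction(self):
        assert predict_interface_residues(_chain("s", [])).predicted_residues == frozenset()

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        ch = _random_chain(rng, "s", 20)
        p1 = predict_interface_residues(ch)
        p2 = predict_interface_residues(ch)
        assert p1.predicted_residues == p2.predicted_residues

    def test_single_hydrophobic_exposed_residue_predicted(self):
        """A lone isoleucine: hydrophobicity 1.0 (table max), exposure proxy
        1.0 by convention → combined score 1.0 ≥ cutoff."""
        ch = _chain("s", [[0, 0, 0]], ["ILE"])
        pred = predict_interface_residues(ch, HydrophobicityExposurePredictor())
        assert pred.predicted_residues == {1}

    def test_single_polar_residue_below_raised_cutoff(self):
        # arginine scores 0 on the hydropathy part; only the exposure proxy
        # (1.0 for a lone residue) contributes, giving 0.5 < cutoff 0.6
        ch = _chain("s", [[0, 0, 0]], ["ARG"])
        pred = predict_interface_residues(
            ch, HydrophobicityExposurePredictor(cutoff=0.6)
        )
        assert pred.predicted_residues == frozenset()

    def test_all_residues_predictor(self):
        ch = _chain("s", [[0, 0, 0], [3, 0, 0]])
        assert predict_interface_residues(ch, AllResiduesPredictor()).predicted_residues == {1, 2}


class TestStructurePairScore:
    def _score(self, ca, cb, threshold=6.0):
        a, b = _chain("a", ca), _chain("b", cb)
        pa = predict_interface_residues(a, AllResiduesPredictor())
        pb = predict_interface_residues(b, AllResiduesPredictor())
        return a, pa, b, pb, structure_pair_score(a, pa, b, pb, threshold)

    def test_far_apart_scores_zero(self):
        *_, res = self._score([[0, 0, 0], [3, 0, 0]], [[100, 0, 0], [103, 0, 0]])
        assert res.interaction_score == 0.0
        assert not res.satisfies

    def test_superposed_scores_one(self):
        coords = [[0, 0, 0], [3, 0, 0], [6, 0, 0]]
        *_, res = self._score(coords, coords)
        assert res.interaction_score == 1.0
        assert res.satisfies

    def test_partial_interface_two_of_six(self):
        """One residue per chain within 6 Å → 2/6 ≈ 0.333, satisfying at 10%."""
        ca = [[0, 0, 0], [50, 0, 0], [60, 0, 0]]
        cb = [[5, 0, 0], [150, 0, 0], [160, 0, 0]]
        *_, res = self._score(ca, cb)
        assert res.interacting_count == 2
        assert res.probable_count == 6
        assert res.interaction_score == pytest.approx(2 / 6)
        assert res.satisfies

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            na, nb = rng.integers(1, 15, size=2)
            a, pa, b, pb, res = self._score(
                rng.uniform(-15, 15, (na, 3)), rng.uniform(-15, 15, (nb, 3))
            )
            inter, prob = structure_score_bruteforce(
                a.coords, [i - 1 for i in sorted(pa.predicted_residues)],
                b.coords, [i - 1 for i in sorted(pb.predicted_residues)],
                6.0,
            )
            assert (res.interacting_count, res.probable_count) == (inter, prob)

    def test_symmetric_under_chain_swap(self):
        rng = np.random.default_rng(4)
        ca, cb = rng.uniform(-10, 10, (8, 3)), rng.uniform(-10, 10, (6, 3))
        *_, r1 = self._score(ca, cb)
        *_, r2 = self._score(cb, ca)
        assert r1.interaction_score == r2.interaction_score

    def test_rigid_translation_kills_score(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            coords = np.random.default_rng(seed).uniform(-10, 10, (12, 3))
            *_, near = self._score(coords, coords + [2.0, 0, 0])
            *_, far = self._score(coords, coords + [60.0, 0, 0])
            assert near.interaction_score > 0
            assert far.interaction_score == 0.0

    def test_no_probable_residues_flagged_undefined(self):
        a, b = _chain("a", [[0, 0, 0]], ["ARG"]), _chain("b", [[1, 0, 0]], ["ARG"])
        strict = HydrophobicityExposurePredictor(cutoff=0.9)
        pa = predict_interface_residues(a, strict)
        pb = predict_interface_residues(b, strict)
        res = structure_pair_score(a, pa, b, pb)
        assert res.interaction_score is None
        assert not res.satisfies


class TestPairCall:
    def _results(self, n_sat, n_tot):
        mk = lambda s: __import__("tfnetminer.structure_interaction", fromlist=["x"]).StructurePairResult(
            ("a", "b"), 1 if s else 0, 10, 0.1 if s else 0.0, s
        )
        return [mk(True)] * n_sat + [mk(False)] * (n_tot - n_sat)

    def test_none_satisfying_not_interacting(self):
        call = pair_interaction_call(("p", "q"), self._results(0, 10))
        assert call.structure_fraction == 0.0
        assert call.is_interacting is False

    def test_all_satisfying_interacting(self):
        call = pair_interaction_call(("p", "q"), self._results(10, 10))
        assert call.structure_fraction == 1.0
        assert call.is_interacting is True

    def test_threshold_is_inclusive_at_30_percent(self):
        call = pair_interaction_call(("p", "q"), self._results(3, 10))
        assert call.structure_fraction == pytest.approx(0.30)
        assert call.is_interacting is True

    def test_no_structures_is_distinct_outcome(self):
        call = pair_interaction_call(("p", "q"), [])
        assert call.no_structural_evidence
        assert call.is_interacting is None


class TestFixtureGeometry:
    def test_planted_dimers_interact_and_decoys_never(self, tmp_path):
        for seed in (0, 1, 2):
            cfg = FixtureConfig(seed=seed)
            out = tmp_path / f"s{seed}"
            mapping, truth = generate_structures(cfg, out)
            by_entry = {}
            for prot, pdb_id, chain in mapping:
                by_entry.setdefault(pdb_id, {})[chain] = prot
            for pdb_id in sorted(by_entry):
                a = read_chain(out / f"{pdb_id.lower()}.pdb", "A")
                b = read_chain(out / f"{pdb_id.lower()}.pdb", "B")
                from scipy.spatial.distance import cdist

                dmin = cdist(a.coords, b.coords).min()
                decoy = int(pdb_id[-1]) >= cfg.structures_per_pair - cfg.structure_decoys_per_pair
                if decoy:
                    assert dmin > 6.0
                else:
                    assert dmin <= cfg.interface_distance + 0.5
                pa = predict_interface_residues(a, AllResiduesPredictor())
                pb = predict_interface_residues(b, AllResiduesPredictor())
                res = structure_pair_score(a, pa, b, pb)
                assert res.satisfies == (not decoy)

    def test_pdb_round_trip_preserves_coordinates(self, tmp_path):
        cfg = FixtureConfig(seed=5)
        mapping, _ = generate_structures(cfg, tmp_path / "rt")
        pdb_id = mapping[0][1]
        ch = read_chain(tmp_path / "rt" / f"{pdb_id.lower()}.pdb", "A")
        assert len(ch.residues) == cfg.n_residues
        # PDB format prints 3 decimals
        assert np.all(np.isfinite(ch.coords))
        assert abs(ch.coords[0, 2] - 0.0) < 0.2  # helix starts near z = 0


def test_non_increasing_residue_index_rejected():
    with pytest.raises(DataError):
        ChainStructure("s", "p", [Residue(2, "ALA", (0, 0, 0)), Residue(1, "ALA", (1, 0, 0))])
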