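"""Interaction-graph network: layers, encoders, attention, GCN semantics."""

import numpy as np
import pytest

from trialselect._autodiff import Tensor
from trialselect.hintnet import (InteractionGraphModel, ModelConfig,
                                 NODE_NAMES, K_NODES, default_adjacency)
from trialselect.hintnet.layers import Highway, Linear, MLP, bce_loss
from trialselect.hintnet.encoders import (MoleculeEncoder, DiseaseEncoder,
                                          ProtocolEncoder,
                                          hashed_sentence_vector,
                                          morgan_fingerprint)
from trialselect.hintnet.model import gcn_forward, ADMET_PROPERTIES
from trialselect.hintnet.records import TrialRecord, Ontology
from trialselect.synthgen import gen_ontology


@pytest.fixture
def model(small_dataset):
    _, _, _, ontology = small_dataset
    return InteractionGraphModel(ModelConfig(d=16, seed=0), ontology)


class TestRecords:
    def test_trial_invariants(self):
        with pytest.raises(ValueError):
            TrialRecord("T0", [], ["R00"])
        with pytest.raises(ValueError):
            TrialRecord("T0", ["CCO"], [])
        with pytest.raises(ValueError):
            TrialRecord("T0", ["CCO"], ["R00"], phase="IV")
        import datetime as dt
        with pytest.raises(ValueError):
            TrialRecord("T0", ["CCO"], ["R00"],
                        start_date=dt.date(2020, 1, 2),
                        completion_date=dt.date(2020, 1, 1))

    def test_ontology_rejects_cycle_and_multiroot(self):
        with pytest.raises(ValueError, match="cycle"):
            Ontology([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError, match="root"):
            Ontology([("A", "R1"), ("B", "R2")])
        with pytest.raises(ValueError, match="self-edge"):
            Ontology([("A", "A")])


class TestHighway:
    def test_gate_limits(self, rng):
        layer = Highway(8, rng)
        x = Tensor(rng.normal(size=(3, 8)))
        layer.gate.b.data[:] = -1e6  # carry only
        assert np.allclose(layer(x).data, x.data)
        layer.gate.b.data[:] = 1e6  # transform only
        h = np.tanh(x.data @ layer.transform.W.data + layer.transform.b.data)
        assert np.allclose(layer(x).data, h)

    def test_hand_computed_formula(self, rng):
        layer = Highway(4, rng)
        x = np.zeros((1, 4))
        t = 1 / (1 + np.exp(-layer.gate.b.data))
        h = np.tanh(layer.transform.b.data)
        expected = t * h  # carry term vanishes at x = 0
        assert np.allclose(layer(Tensor(x)).data, expected)


class TestHeads:
    def test_bce_closed_form(self):
        loss = bce_loss(Tensor(np.array([0.5])), np.array([1.0]))
        assert loss.data == pytest.approx(np.log(2), abs=1e-9)

    def test_admet_head_outputs_open_interval(self, model, rng):
        e = Tensor(rng.normal(size=(5, 16)))
        for prop in ADMET_PROPERTIES:
            emb, prob = model.admet_head(e, prop)
            assert emb.shape == (5, 16)
            assert np.all((prob.data > 0) & (prob.data < 1))
        with pytest.raises(ValueError):
            model.admet_head(e, "solubility")

    def test_disease_risk_head_deterministic(self, model, rng):
        e = Tensor(rng.normal(size=(4, 16)))
        _, p1 = model.disease_risk_head(e)
        _, p2 = model.disease_risk_head(e)
        assert np.array_equal(p1.data, p2.data)
        assert np.all((p1.data > 0) & (p1.data < 1))


class TestEncoders:
    def test_drug_mean_invariances(self, model):
        enc = model.mol_encoder
        single = enc.encode([["CCO"]]).data
        duplicated = enc.encode([["CCO", "CCO"]]).data
        assert np.allclose(single, duplicated)
        u = enc.encode([["CCO"]]).data
        v = enc.encode([["c1ccccc1"]]).data
        both = enc.encode([["CCO", "c1ccccc1"]]).data
        assert np.allclose(both, (u + v) / 2, atol=1e-10)

    def test_unparseable_smiles_names_offender(self, model):
        with pytest.raises(ValueError, match="not_a_molecule"):
            model.mol_encoder.encode([["not_a_molecule"]])

    def test_gram_attention_normalizes(self, model, small_dataset):
        _, _, _, ontology = small_dataset
        enc = model.dis_encoder
        for code in list(ontology.leaves())[:3]:
            weights = enc.attention_weights(code)
            assert set(weights) == set(ontology.ancestors(code))
            assert sum(weights.values()) == pytest.approx(1.0)

    def test_root_only_ontology_embeds_to_own_basis(self, rng):
        ont = gen_ontology(0, 1)
        enc = DiseaseEncoder(8, ont, rng)
        emb = enc.code_embeddings().data
        assert np.allclose(emb, enc.basis.data)

    def test_mean_of_two_codes(self, model, small_dataset):
        _, _, _, ontology = small_dataset
        enc = model.dis_encoder
        codes = ontology.leaves()[:2]
        single = [enc.encode([[c]]).data for c in codes]
        pair = enc.encode([codes]).data
        assert np.allclose(pair, (single[0] + single[1]) / 2)

    def test_unknown_code_rejected(self, model):
        with pytest.raises(KeyError, match="XYZ"):
            model.dis_encoder.encode([["XYZ"]])

    def test_protocol_shape_and_determinism(self, rng):
        enc = ProtocolEncoder(12, np.random.default_rng(3))
        proto = [("+", "adults aged 30 to 65 years"),
                 ("-", "pregnant or breastfeeding")]
        a = enc.encode([proto]).data
        b = enc.encode([proto]).data
        assert a.shape == (1, 12)
        assert np.array_equal(a, b)
        # variable criterion counts share the output dimension
        out = enc.encode([proto, proto * 3]).data
        assert out.shape == (2, 12)

    def test_empty_protocol_warns_and_zeroes(self, rng):
        enc = ProtocolEncoder(8, rng)
        with pytest.warns(UserWarning):
            x, mask = enc.featurize([[]])
        assert np.allclose(x, 0.0)

    def test_hashed_sentences_are_stable(self):
        v1 = hashed_sentence_vector("stable baseline medication", 32)
        v2 = hashed_sentence_vector("stable baseline medication", 32)
        assert np.array_equal(v1, v2)
        assert not np.array_equal(
            v1, hashed_sentence_vector("different sentence entirely", 32))


class TestGraph:
    def test_node_matrix_has_all_thirteen_rows(self, model, small_dataset):
        _, trials, _, _ = small_dataset
        assert K_NODES == 13 and len(NODE_NAMES) == 13
        E0 = model.node_matrix(model.encode_batch(trials[:4]))
        assert E0.shape == (4, 13, 16)
        assert np.all(np.isfinite(E0.data))

    def test_adjacency_symmetric_with_self_loops(self):
        J = default_adjacency()
        assert np.array_equal(J, J.T)
        assert np.all(np.diag(J) == 1)

    def test_attention_in_open_interval(self, model, small_dataset):
        _, trials, _, _ = small_dataset
        E0 = model.node_matrix(model.encode_batch(trials[:3]))
        A = model.attention_matrix(E0)
        assert np.all((A.data > 0) & (A.data < 1))

    def test_attention_symmetric_for_identical_rows(self, model, rng):
        E0 = np.tile(rng.normal(size=(1, 1, 16)), (1, 13, 1))
        A = model.attention_matrix(Tensor(E0))
        assert A.data[0, 2, 5] == pytest.approx(A.data[0, 5, 2])

    def test_gcn_matches_dense_oracle(self, model):
        """Per-node loop re-derivation of the masked attentive update."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            E0 = r.normal(size=(13, 16))
            A = r.uniform(size=(13, 13))
            J = (r.uniform(size=(13, 13)) < 0.4).astype(float)
            Ws = [r.normal(size=(16, 16)) for _ in range(2)]
            Bs = [r.normal(size=(13, 16)) for _ in range(2)]
            got = gcn_forward(E0, J, A, Ws, Bs)
            E = E0
            for W, B in zip(Ws, Bs):
                nxt = np.zeros_like(E)
                for i in range(13):
                    msg = np.zeros(16)
                    for k in range(13):
                        msg += A[i, k] * J[i, k] * E[k]
                    nxt[i] = np.maximum(0.0, B[i] + msg @ W)
                E = nxt
            assert np.abs(got - E).max() < 1e-6

    def test_zero_mask_reduces_to_bias(self, model, rng):
        E0 = rng.normal(size=(13, 16))
        Bs = [b.data for b in model.gcn_B]
        Ws = [w.data for w in model.gcn_W]
        out = gcn_forward(E0, np.zeros((13, 13)), np.ones((13, 13)), Ws[:1],
                          Bs[:1])
        assert np.allclose(out, np.maximum(0.0, Bs[0]))

    def test_edge_ablation_blocks_message(self):
        """With edge (i, j) removed, node j's one-layer output ignores
        arbitrary perturbations of node i (property over 20 seeds)."""
        i, j = 1, 9  # drug -> pk has no direct construction edge
        for seed in range(20):
            r = np.random.default_rng(seed)
            J = default_adjacency().copy()
            J[i, j] = J[j, i] = 0.0
            A = r.uniform(size=(13, 13))
            W = [r.normal(size=(8, 8))]
            B = [r.normal(size=(13, 8))]
            E0 = r.normal(size=(13, 8))
            base = gcn_forward(E0, J, A, W, B)
            E0_perturbed = E0.copy()
            E0_perturbed[i] = r.normal(size=8) * 100
            out = gcn_forward(E0_perturbed, J, A, W, B)
            assert np.allclose(base[j], out[j])

    def test_forward_probability_and_report(self, model, small_dataset):
        _, trials, _, _ = small_dataset
        prob, report = model.predict(trials[0])
        assert 0.0 < prob < 1.0
        assert all(0.0 < e["weight"] < 1.0 for e in report.edges)
        # off-diagonal construction edges both ways, excluding self-loops
        expected_edges = int(default_adjacency().sum() - 13)
        assert len(report.edges) == expected_edges
        dot = report.to_dot()
        assert dot.startswith("digraph") and '"pk" -> "prediction"' in dot

    def test_forward_deterministic_under_seed(self, small_dataset):
        _, trials, _, ontology = small_dataset
        m1 = InteractionGraphModel(ModelConfig(d=8, seed=11), ontology)
        m2 = InteractionGraphModel(ModelConfig(d=8, seed=11), ontology)
        p1 = m1.predict_proba(trials[:10])
        p2 = m2.predict_proba(trials[:10])
        assert np.array_equal(p1, p2)


class TestCheckpoint:
    def test_save_load_round_trip(self, model, small_dataset, tmp_path):
        _, trials, _, _ = small_dataset
        path = tmp_path / "model.npz"
        model.save(path)
        back = InteractionGraphModel.load(path)
        assert np.array_equal(back.predict_proba(trials[:5]),
                              model.predict_proba(trials[:5]))

    def test_corrupt_checkpoint_reports_version_error(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, junk=np.zeros(3))
        with pytest.raises(ValueError, match="corrupt|version"):
            InteractionGraphModel.load(path)
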