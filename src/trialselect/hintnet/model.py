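"""The 13-node hierarchical interaction graph and its attentive GCN.

Nodes sit in four tiers: input (disease, drug, protocol), pretrained
knowledge (five ADMET properties, disease risk), aggregation (PK,
interaction, augmented interaction) and the prediction node.  Layer-0 node
embeddings are wired through a graph convolution whose messages are gated by
a learned edge-attention matrix; the approval probability is read off the
prediction node after N rounds of propagation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .._autodiff import Tensor, concat, stack
from .layers import Module, Linear, HighwayStack, MLP
from .records import Ontology, TrialRecord, NODE_NAMES, K_NODES
from .encoders import MoleculeEncoder, DiseaseEncoder, ProtocolEncoder

__all__ = ["ModelConfig", "InteractionGraphModel", "AttentionReport",
           "default_adjacency", "gcn_forward", "ADMET_PROPERTIES"]

ADMET_PROPERTIES = ("absorption", "distribution", "metabolism",
                    "excretion", "toxicity")

_NODE_INDEX = {name: i for i, name in enumerate(NODE_NAMES)}

# Tier wiring of the interaction graph: knowledge heads read the input
# nodes, aggregation nodes read their tiers, the prediction node reads PK
# and the augmented interaction.  Symmetrized, with self-loops so a node
# retains its own state under the unnormalized GCN update.
_CONSTRUCTION_EDGES = [
    ("drug", "absorption"), ("drug", "distribution"), ("drug", "metabolism"),
    ("drug", "excretion"), ("drug", "toxicity"),
    ("disease", "disease_risk"),
    ("absorption", "pk"), ("distribution", "pk"), ("metabolism", "pk"),
    ("excretion", "pk"), ("toxicity", "pk"),
    ("drug", "interaction"), ("disease", "interaction"),
    ("protocol", "interaction"),
    ("disease_risk", "augmented"), ("interaction", "augmented"),
    ("pk", "prediction"), ("augmented", "prediction"),
]

CHECKPOINT_VERSION = 1


def default_adjacency() -> np.ndarray:
    """Symmetric 13x13 adjacency with unit diagonal."""
    J = np.eye(K_NODES)
    for a, b in _CONSTRUCTION_EDGES:
        i, j = _NODE_INDEX[a], _NODE_INDEX[b]
        J[i, j] = J[j, i] = 1.0
    return J


def gcn_forward(E0: np.ndarray, J: np.ndarray, A: np.ndarray,
                weights: list[np.ndarray], biases: list[np.ndarray]) -> np.ndarray:
    """Attentive GCN update E(n) = ReLU(B(n) + (A o J) E(n-1) W(n)).

    `o` is element-wise multiplication, so messages flow only along edges of
    the adjacency J, each scaled by its attention weight.  Accepts a single
    (K, d) instance or a batch (n, K, d); A likewise (K, K) or (n, K, K).
    """
    E = np.asarray(E0, dtype=float)
    M = np.asarray(A, dtype=float) * np.asarray(J, dtype=float)
    for W, B in zip(weights, biases):
        E = np.maximum(0.0, B + M @ E @ W)
    return E


@dataclass
class ModelConfig:
    d: int = 64
    n_gcn_layers: int = 2
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AttentionReport:
    """Per-edge attention weights of one trial's interaction graph."""

    trial_id: str
    edges: list[dict]  # {"src": name, "dst": name, "weight": float}

    def to_json(self) -> str:
        return json.dumps({"trial_id": self.trial_id, "edges": self.edges},
                          indent=2)

    def to_dot(self) -> str:
        lines = ["digraph interaction {"]
        for e in self.edges:
            if e["src"] == e["dst"]:
                continue
            lines.append(
                f'  "{e["src"]}" -> "{e["dst"]}" '
                f'[label="{e["weight"]:.3f}", penwidth={0.5 + 4 * e["weight"]:.2f}];')
        lines.append("}")
        return "\n".join(lines)


class InteractionGraphModel(Module):
    """Encoders, knowledge heads, aggregation nodes, attention and GCN."""

    def __init__(self, config: ModelConfig, ontology: Ontology):
        self.config = config
        self.ontology = ontology
        d = config.d
        rng = np.random.default_rng(config.seed)
        self.J = default_adjacency()

        self.mol_encoder = MoleculeEncoder(d, rng)
        self.dis_encoder = DiseaseEncoder(d, ontology, rng)
        self.prot_encoder = ProtocolEncoder(d, rng)

        # independent ADMET heads: e_* = Phi_*(e_drug), score via 1-layer FCNN
        self.admet_phi = {p: Linear(d, d, rng) for p in ADMET_PROPERTIES}
        self.admet_out = {p: Linear(d, 1, rng) for p in ADMET_PROPERTIES}
        # disease risk: 2-layer highway, then 1-layer FCNN
        self.risk_psi = HighwayStack(d, 2, rng)
        self.risk_out = Linear(d, 1, rng)

        # aggregation nodes: FC to d then 2-layer highway
        self.pk_fc = Linear(5 * d, d, rng)
        self.pk_hw = HighwayStack(d, 2, rng)
        self.in_fc = Linear(3 * d, d, rng)
        self.in_hw = HighwayStack(d, 2, rng)
        self.au_fc = Linear(2 * d, d, rng)
        self.au_hw = HighwayStack(d, 2, rng)
        self.pr_fc = Linear(2 * d, d, rng)
        self.pr_hw = HighwayStack(d, 2, rng)

        # edge-attention scorer: 2-layer, ReLU hidden, sigmoid output
        self.att_scorer = MLP([2 * d, d, 1], rng, out_sigmoid=True)

        # GCN parameters per layer
        self.gcn_W = [Tensor(rng.normal(0, np.sqrt(1.0 / d), size=(d, d)),
                             requires_grad=True)
                      for _ in range(config.n_gcn_layers)]
        self.gcn_B = [Tensor(np.zeros((K_NODES, d)), requires_grad=True)
                      for _ in range(config.n_gcn_layers)]

        self.final = Linear(d, 1, rng)

    # -- parameter bookkeeping (dict-valued members need explicit handling) --
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        params += self.mol_encoder.parameters()
        params += self.dis_encoder.parameters()
        params += self.prot_encoder.parameters()
        for p in ADMET_PROPERTIES:
            params += self.admet_phi[p].parameters()
            params += self.admet_out[p].parameters()
        params += self.risk_psi.parameters()
        params += self.risk_out.parameters()
        for m in (self.pk_fc, self.pk_hw, self.in_fc, self.in_hw,
                  self.au_fc, self.au_hw, self.pr_fc, self.pr_hw,
                  self.att_scorer, self.final):
            params += m.parameters()
        params += self.gcn_W
        params += self.gcn_B
        return params

    # -- heads ---------------------------------------------------------------
    def admet_head(self, e_drug: Tensor, prop: str) -> tuple[Tensor, Tensor]:
        """(knowledge-node embedding, property probability) for one ADMET task."""
        if prop not in ADMET_PROPERTIES:
            raise ValueError(f"unknown ADMET property {prop!r}")
        e = self.admet_phi[prop](e_drug).tanh()
        prob = self.admet_out[prop](e).sigmoid()
        return e, prob

    def disease_risk_head(self, e_disease: Tensor) -> tuple[Tensor, Tensor]:
        e = self.risk_psi(e_disease)
        prob = self.risk_out(e).sigmoid()
        return e, prob

    def aggregate(self, e_drug: Tensor, e_disease: Tensor, e_protocol: Tensor,
                  admet_embs: list[Tensor], e_risk: Tensor):
        """PK, interaction, augmented-interaction and prediction embeddings."""
        e_pk = self.pk_hw(self.pk_fc(concat(admet_embs, axis=-1)))
        e_in = self.in_hw(self.in_fc(
            concat([e_drug, e_disease, e_protocol], axis=-1)))
        e_au = self.au_hw(self.au_fc(concat([e_risk, e_in], axis=-1)))
        e_pr = self.pr_hw(self.pr_fc(concat([e_pk, e_au], axis=-1)))
        return e_pk, e_in, e_au, e_pr

    # -- graph ---------------------------------------------------------------
    def node_matrix(self, trials_features) -> Tensor:
        """Layer-0 node embedding matrix E(0), shape (batch, 13, d)."""
        e_drug, e_disease, e_protocol = trials_features
        admet = []
        for p in ADMET_PROPERTIES:
            e, _ = self.admet_head(e_drug, p)
            admet.append(e)
        e_risk, _ = self.disease_risk_head(e_disease)
        e_pk, e_in, e_au, e_pr = self.aggregate(
            e_drug, e_disease, e_protocol, admet, e_risk)
        rows = {
            "disease": e_disease, "drug": e_drug, "protocol": e_protocol,
            "absorption": admet[0], "distribution": admet[1],
            "metabolism": admet[2], "excretion": admet[3],
            "toxicity": admet[4], "disease_risk": e_risk,
            "pk": e_pk, "interaction": e_in, "augmented": e_au,
            "prediction": e_pr,
        }
        return stack([rows[name] for name in NODE_NAMES], axis=1)

    def attention_matrix(self, E0: Tensor) -> Tensor:
        """Pairwise edge-importance matrix from layer-0 embeddings only."""
        b, k, d = E0.shape
        left = E0.reshape(b, k, 1, d) + Tensor(np.zeros((1, 1, k, 1)))
        right = E0.reshape(b, 1, k, d) + Tensor(np.zeros((1, k, 1, 1)))
        pair = concat([left, right], axis=-1)      # (b, k, k, 2d)
        return self.att_scorer(pair).reshape(b, k, k)

    def gcn(self, E0: Tensor, A: Tensor) -> Tensor:
        masked = A * Tensor(self.J)
        E = E0
        for W, B in zip(self.gcn_W, self.gcn_B):
            E = (B + masked @ E @ W).relu()
        return E

    # -- end to end ----------------------------------------------------------
    def encode_batch(self, trials: list[TrialRecord]):
        e_drug = self.mol_encoder.encode([t.drugs for t in trials])
        e_disease = self.dis_encoder.encode([t.diseases for t in trials])
        e_protocol = self.prot_encoder.encode([t.protocol for t in trials])
        return e_drug, e_disease, e_protocol

    def forward_from_embeddings(self, triple, return_attention: bool = False):
        """Forward pass from precomputed (drug, disease, protocol) embeddings."""
        E0 = self.node_matrix(triple)
        A = self.attention_matrix(E0)
        EN = self.gcn(E0, A)
        e_pr = EN[:, _NODE_INDEX["prediction"], :]
        n = E0.shape[0]
        prob = self.final(e_pr).sigmoid().reshape(n)
        if return_attention:
            return prob, A
        return prob

    def forward(self, trials: list[TrialRecord],
                return_attention: bool = False):
        """Approval probabilities (batch,) and optionally attention matrices."""
        return self.forward_from_embeddings(self.encode_batch(trials),
                                            return_attention=return_attention)

    def predict_proba(self, trials: list[TrialRecord],
                      batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(trials), batch_size):
            out.append(self.forward(trials[i:i + batch_size]).data)
        return np.concatenate(out) if out else np.zeros(0)

    def predict(self, trial: TrialRecord) -> tuple[float, AttentionReport]:
        """Approval probability and the per-edge attention report."""
        try:
            prob, A = self.forward([trial], return_attention=True)
        except (ValueError, KeyError) as err:
            raise type(err)(f"trial {trial.trial_id}: {err}") from err
        a = A.data[0]
        edges = []
        for i in range(K_NODES):
            for j in range(K_NODES):
                if self.J[i, j] and i != j:
                    edges.append({"src": NODE_NAMES[i], "dst": NODE_NAMES[j],
                                  "weight": float(a[i, j])})
        return float(prob.data[0]), AttentionReport(trial.trial_id, edges)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        meta = {"version": CHECKPOINT_VERSION,
                "config": self.config.to_dict(),
                "ontology_edges": self.ontology.parent_edges()}
        np.savez_compressed(path, _meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "InteractionGraphModel":
        with np.load(path) as archive:
            try:
                meta = json.loads(bytes(archive["_meta"]).decode())
            except (KeyError, ValueError) as err:
                raise ValueError(f"corrupt checkpoint {path}: {err}") from err
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version mismatch: file has "
                    f"{meta.get('version')}, expected {CHECKPOINT_VERSION}")
            ontology = Ontology(
                [tuple(e) for e in meta["ontology_edges"]]) \
                if meta["ontology_edges"] else Ontology.single_root()
            model = cls(ModelConfig(**meta["config"]), ontology)
            n = len(model.parameters())
            model.load_state_arrays([archive[f"p{i}"] for i in range(n)])
        return model
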