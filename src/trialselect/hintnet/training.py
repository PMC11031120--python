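"""Three-stage training: ADMET pretraining, disease-risk pretraining,
end-to-end fine-tuning on labeled trials with binary cross-entropy."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .._autodiff import Tensor
from .layers import Adam, bce_loss
from .model import InteractionGraphModel, ModelConfig, ADMET_PROPERTIES
from .records import TrialRecord, Ontology

__all__ = ["TrainConfig", "train", "pretrain_admet", "pretrain_disease_risk"]

log = logging.getLogger("trialselect.train")


@dataclass
class TrainConfig:
    epochs: int = 20
    pretrain_epochs: int = 8
    lr: float = 1e-3
    batch_size: int = 32
    val_fraction: float = 0.15  # held out from the training set for early stopping
    patience: int = 8
    swa_top_k: int = 5  # average the parameters of the k best validation epochs
    seed: int = 0


def _as_pairs(table) -> list[tuple[str, int]]:
    """Accept a DataFrame with (smiles|code, label) columns or pair list."""
    if hasattr(table, "itertuples"):
        cols = list(table.columns)
        return [(str(getattr(r, cols[0])), int(getattr(r, cols[1])))
                for r in table.itertuples(index=False)]
    return [(str(a), int(b)) for a, b in table]


def pretrain_admet(model: InteractionGraphModel, tables: dict,
                   config: TrainConfig) -> list[float]:
    """Warm-start the molecule encoder and the five ADMET heads.

    `tables` maps property name -> (smiles, binary label) table.  Returns
    the per-epoch mean loss across properties.
    """
    rng = np.random.default_rng(config.seed + 1)
    params = model.mol_encoder.parameters()
    for p in ADMET_PROPERTIES:
        params += model.admet_phi[p].parameters()
        params += model.admet_out[p].parameters()
    opt = Adam(params, lr=config.lr)
    data = {p: _as_pairs(t) for p, t in tables.items() if p in ADMET_PROPERTIES}
    if not data:
        raise ValueError("no ADMET tables supplied")
    # featurize once; fingerprints are cached inside the encoder
    feats = {p: model.mol_encoder.featurize([[s] for s, _ in rows])
             for p, rows in data.items()}
    labels = {p: np.array([y for _, y in rows], dtype=float)
              for p, rows in data.items()}
    history = []
    for epoch in range(config.pretrain_epochs):
        losses = []
        for p, rows in data.items():
            idx = rng.permutation(len(rows))
            for start in range(0, len(rows), config.batch_size):
                batch = idx[start:start + config.batch_size]
                e_drug = model.mol_encoder(feats[p][batch])
                _, prob = model.admet_head(e_drug, p)
                loss = bce_loss(prob.reshape(len(batch)), labels[p][batch])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        log.info("admet pretrain epoch %d loss %.4f", epoch, history[-1])
    return history


def pretrain_disease_risk(model: InteractionGraphModel, table,
                          config: TrainConfig) -> list[float]:
    """Warm-start the disease encoder and risk head on historical outcomes.

    `table` rows are (ontology code, binary success label) from earlier
    trials; the head learns each disease's historical approval tendency.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = _as_pairs(table)
    if not rows:
        raise ValueError("empty disease-risk table")
    params = (model.dis_encoder.parameters() + model.risk_psi.parameters()
              + model.risk_out.parameters())
    opt = Adam(params, lr=config.lr)
    trial_m = model.dis_encoder.trial_matrix([[c] for c, _ in rows])
    labels = np.array([y for _, y in rows], dtype=float)
    history = []
    for epoch in range(config.pretrain_epochs):
        idx = rng.permutation(len(rows))
        losses = []
        for start in range(0, len(rows), config.batch_size):
            batch = idx[start:start + config.batch_size]
            e_dis = Tensor(trial_m[batch]) @ model.dis_encoder.code_embeddings()
            _, prob = model.disease_risk_head(e_dis)
            loss = bce_loss(prob.reshape(len(batch)), labels[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        log.info("disease-risk pretrain epoch %d loss %.4f", epoch, history[-1])
    return history


def _precompute(model: InteractionGraphModel, trials: list[TrialRecord]):
    mol = model.mol_encoder.featurize([t.drugs for t in trials])
    dis = model.dis_encoder.trial_matrix([t.diseases for t in trials])
    prot_x, prot_mask = model.prot_encoder.featurize([t.protocol for t in trials])
    return mol, dis, prot_x, prot_mask


def _batch_forward(model, feats, batch_idx, return_attention=False):
    mol, dis, prot_x, prot_mask = feats
    e_drug = model.mol_encoder(mol[batch_idx])
    e_dis = Tensor(dis[batch_idx]) @ model.dis_encoder.code_embeddings()
    e_prot = model.prot_encoder(prot_x[batch_idx], prot_mask[batch_idx])
    return model.forward_from_embeddings((e_drug, e_dis, e_prot),
                                         return_attention=return_attention)


def train(trials: list[TrialRecord], ontology: Ontology,
          model_config: ModelConfig | None = None,
          config: TrainConfig | None = None,
          admet_tables: dict | None = None,
          risk_table=None,
          model: InteractionGraphModel | None = None):
    """Fit the interaction network; returns (model, history dict).

    Stages: (1) ADMET pretraining on auxiliary molecule tables, (2)
    disease-risk pretraining on historical per-disease outcomes, (3)
    end-to-end fine-tuning of all parameters on the labeled trials.  Stages
    1-2 are skipped when their tables are absent.  Fully seeded.
    """
    if not trials:
        raise ValueError("empty training set")
    unlabeled = [t.trial_id for t in trials if t.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled training trials: {unlabeled[:5]}")
    labels = np.array([t.label for t in trials], dtype=float)
    if len(np.unique(labels)) == 1:
        warnings.warn("training labels are all one class; proceeding anyway")

    model_config = model_config or ModelConfig()
    config = config or TrainConfig(seed=model_config.seed)
    if model is None:
        model = InteractionGraphModel(model_config, ontology)
    history: dict[str, list[float]] = {}

    if admet_tables:
        history["admet"] = pretrain_admet(model, admet_tables, config)
    if risk_table is not None:
        history["disease_risk"] = pretrain_disease_risk(model, risk_table, config)

    rng = np.random.default_rng(config.seed + 3)
    feats = _precompute(model, trials)
    n = len(trials)
    # hold out a validation slice for early stopping when both classes allow
    perm = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    use_val = (n_val >= 10 and len(np.unique(labels[val_idx])) == 2
               and len(fit_idx) > 0)
    if not use_val:
        fit_idx = perm

    opt = Adam(model.parameters(), lr=config.lr)
    history["classify"] = []
    history["val_auc"] = []
    best_auc, since_best = -np.inf, 0
    snapshots: list[tuple[float, list[np.ndarray]]] = []
    for epoch in range(config.epochs):
        idx = fit_idx[rng.permutation(len(fit_idx))]
        losses = []
        for start in range(0, len(idx), config.batch_size):
            batch = idx[start:start + config.batch_size]
            prob = _batch_forward(model, feats, batch)
            loss = bce_loss(prob, labels[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["classify"].append(float(np.mean(losses)))
        if use_val:
            val_prob = _batch_forward(model, feats, val_idx).data
            from sklearn.metrics import roc_auc_score
            val_auc = float(roc_auc_score(labels[val_idx], val_prob))
            history["val_auc"].append(val_auc)
            snapshots.append((val_auc,
                              [p.data.copy() for p in model.parameters()]))
            snapshots.sort(key=lambda t: -t[0])
            del snapshots[max(1, config.swa_top_k):]
            if val_auc > best_auc:
                best_auc, since_best = val_auc, 0
            else:
                since_best += 1
            log.info("fine-tune epoch %d loss %.4f val_auc %.4f",
                     epoch, history["classify"][-1], val_auc)
            if since_best >= config.patience:
                log.info("early stop at epoch %d (best val_auc %.4f)",
                         epoch, best_auc)
                break
        else:
            log.info("fine-tune epoch %d loss %.4f",
                     epoch, history["classify"][-1])
    if snapshots:
        # stochastic-weight-averaging over the best validation epochs
        averaged = [np.mean([s[1][i] for s in snapshots], axis=0)
                    for i in range(len(snapshots[0][1]))]
        model.load_state_arrays(averaged)
    return model, history
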