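"""File formats, run configuration and the end-to-end pipeline.

CSV dialect: UTF-8, comma-separated, quoted where needed; multi-valued
cells (drugs, disease codes) are semicolon-joined; eligibility criteria are
a JSON list of [tag, sentence] pairs with tag '+' (inclusion) or '-'
(exclusion).  Dates are ISO-8601.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .hintnet.records import TrialRecord, Ontology
from .hintnet.model import ModelConfig
from .hintnet.training import TrainConfig, train
from . import riskcal, evalkit
from .riskcal import ScoredSample, ABSTAIN

__all__ = ["read_trials", "write_trials", "read_ontology", "write_ontology",
           "read_admet_table", "read_scores", "write_scores",
           "write_decisions", "RunConfig", "run_pipeline"]

log = logging.getLogger("trialselect.io")

TRIAL_COLUMNS = ["trial_id", "smiles", "icd_codes", "criteria", "phase",
                 "start_date", "completion_date", "label"]


def _parse_date(text: str) -> _dt.date | None:
    return _dt.date.fromisoformat(text) if text else None


def read_trials(path) -> list[TrialRecord]:
    """Read a trial table; malformed rows are skipped with logged line
    numbers, and the run fails if more than 10% of rows are bad."""
    path = Path(path)
    records: list[TrialRecord] = []
    bad = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in TRIAL_COLUMNS[:5] if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {missing}")
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                label_txt = (row.get("label") or "").strip()
                records.append(TrialRecord(
                    trial_id=row["trial_id"],
                    drugs=[s for s in row["smiles"].split(";") if s],
                    diseases=[s for s in row["icd_codes"].split(";") if s],
                    protocol=[(t, s) for t, s in json.loads(row["criteria"] or "[]")],
                    phase=row["phase"],
                    start_date=_parse_date(row.get("start_date") or ""),
                    completion_date=_parse_date(row.get("completion_date") or ""),
                    label=int(label_txt) if label_txt else None))
            except (ValueError, KeyError, json.JSONDecodeError) as err:
                bad += 1
                log.warning("%s line %d skipped: %s", path, lineno, err)
    if n_rows == 0:
        warnings.warn(f"{path}: empty trial table")
    elif bad > 0.1 * n_rows:
        raise ValueError(f"{path}: {bad}/{n_rows} rows malformed")
    return records


def write_trials(trials: list[TrialRecord], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(TRIAL_COLUMNS)
        for t in trials:
            writer.writerow([
                t.trial_id, ";".join(t.drugs), ";".join(t.diseases),
                json.dumps([[tag, s] for tag, s in t.protocol]),
                t.phase,
                t.start_date.isoformat() if t.start_date else "",
                t.completion_date.isoformat() if t.completion_date else "",
                "" if t.label is None else t.label])


def read_ontology(path) -> Ontology:
    """Two-column (child, parent) edge list; '#' starts a comment."""
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path} line {lineno}: expected 'child parent'")
        edges.append((parts[0], parts[1]))
    return Ontology(edges)


def write_ontology(ontology: Ontology, path) -> None:
    lines = ["# child parent"]
    lines += [f"{c} {p}" for c, p in ontology.parent_edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_admet_table(path):
    import pandas as pd
    return pd.read_csv(path)


def read_scores(path) -> list[dict]:
    """Score CSV: trial_id, prob_success[, true_label]."""
    rows = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rows.append({
                "trial_id": row["trial_id"],
                "prob_success": float(row["prob_success"]),
                "true_label": int(row["true_label"])
                if (row.get("true_label") or "").strip() else None})
    return rows


def write_scores(rows: list[dict], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "prob_success", "true_label"])
        for r in rows:
            writer.writerow([r["trial_id"], f"{r['prob_success']:.6f}",
                             "" if r.get("true_label") is None else r["true_label"]])


def write_decisions(trial_ids, decisions, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "decision", "confidence"])
        for tid, d in zip(trial_ids, decisions):
            writer.writerow([tid, d.pred_label if d.kept else ABSTAIN,
                             f"{d.confidence:.6f}"])


@dataclass
class RunConfig:
    """One reproducible end-to-end run; the seed is mandatory."""

    trials_path: str
    ontology_path: str
    out_dir: str
    seed: int
    admet_paths: dict = field(default_factory=dict)  # property -> csv path
    risk_table_path: str | None = None
    d: int = 64
    n_gcn_layers: int = 2
    epochs: int = 20
    pretrain_epochs: int = 8
    lr: float = 1e-3
    batch_size: int = 32
    alpha: float = 0.1
    beta: float = 0.1
    split_date: str = "2013-08-07"
    validation_fraction: float = 0.15
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        obj = yaml.safe_load(Path(path).read_text())
        if "seed" not in obj:
            raise ValueError("config must set an explicit seed")
        return cls(**obj)


def run_pipeline(config: RunConfig) -> dict:
    """simulate-independent pipeline: read, split, train, calibrate,
    predict selectively, evaluate, sweep, explain.  Writes six artifacts to
    out_dir, each stamped with the config hash and seed."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

    trials = _stage("read_trials", lambda: read_trials(config.trials_path))
    ontology = _stage("read_ontology", lambda: read_ontology(config.ontology_path))
    admet = {p: read_admet_table(path) for p, path in config.admet_paths.items()}
    risk_table = (read_admet_table(config.risk_table_path)
                  if config.risk_table_path else None)

    spec = evalkit.SplitSpec(_dt.date.fromisoformat(config.split_date),
                             config.validation_fraction, seed=config.seed)
    train_set, val_set, test_set = _stage(
        "temporal_split", lambda: evalkit.temporal_split(trials, spec))

    model_cfg = ModelConfig(d=config.d, n_gcn_layers=config.n_gcn_layers,
                            seed=config.seed)
    train_cfg = TrainConfig(epochs=config.epochs,
                            pretrain_epochs=config.pretrain_epochs,
                            lr=config.lr, batch_size=config.batch_size,
                            seed=config.seed)
    model, history = _stage("train", lambda: train(
        train_set, ontology, model_cfg, train_cfg,
        admet_tables=admet or None, risk_table=risk_table))
    ckpt_path = out / "checkpoint.npz"
    _stage("checkpoint", lambda: model.save(ckpt_path))

    # calibration on the held-out validation split
    val_probs = model.predict_proba(val_set)
    cal_samples = [ScoredSample.from_prob(p, t.label)
                   for p, t in zip(val_probs, val_set)]
    calib = _stage("calibrate", lambda: riskcal.calibrate(
        cal_samples, alpha=config.alpha, beta=config.beta))
    if not calib.feasible:
        warnings.warn("calibration infeasible: abstaining on all predictions")
    (out / "calibration.json").write_text(
        json.dumps({**stamp, **json.loads(calib.to_json())}, indent=2))

    test_probs = model.predict_proba(test_set)
    lam = calib.lam_hat if calib.feasible else 1.0 + 1e-9
    decisions = riskcal.apply_selective(test_probs, min(lam, 1.0))
    if not calib.feasible:
        decisions = [riskcal.SelectiveDecision(ABSTAIN, d.confidence, False)
                     for d in decisions]
    write_decisions([t.trial_id for t in test_set], decisions,
                    out / "decisions.csv")

    labels = np.array([t.label for t in test_set])
    kept = np.array([d.kept for d in decisions])
    report = _stage("evaluate", lambda: evalkit.metrics_report(
        test_probs, labels, kept=kept if kept.any() else None,
        seed=config.seed))
    (out / "metrics.json").write_text(
        json.dumps({**stamp, **json.loads(report.to_json())}, indent=2))

    test_samples = [ScoredSample.from_prob(p, t.label)
                    for p, t in zip(test_probs, test_set)]
    sweep = evalkit.lambda_sweep(test_samples)
    with (out / "sweep.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lam", "selective_accuracy", "fraction_kept"])
        for lam_, acc_, frac_ in sweep:
            writer.writerow([f"{lam_:.6f}", f"{acc_:.6f}", f"{frac_:.6f}"])

    if test_set:
        _, att = model.predict(test_set[0])
        (out / "attention.dot").write_text(att.to_dot())
    return {"model": model, "history": history, "calibration": calib,
            "report": report, "artifacts": sorted(p.name for p in out.iterdir())}
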