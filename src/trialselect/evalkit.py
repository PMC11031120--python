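"""Evaluation: metrics, temporal splitting, significance and trade-off sweeps.

PR-AUC uses the step-wise (average-precision) convention — precision is not
interpolated between recall levels — and ROC-AUC the trapezoidal rule, so
both agree with their combinatorial definitions (threshold enumeration and
Mann-Whitney pair counting respectively).
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn import metrics as _skm

from .hintnet.records import TrialRecord
from .riskcal import ScoredSample

__all__ = ["MetricsReport", "SplitSpec", "pr_auc", "roc_auc", "f1_accuracy",
           "temporal_split", "bootstrap_pvalue", "lambda_sweep",
           "relative_improvement", "metrics_report"]

log = logging.getLogger("trialselect.eval")


def _check_two_class(labels: np.ndarray, name: str) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError(f"{name} undefined: labels contain a single class")


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve (average precision)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels, "PR-AUC")
    return float(_skm.average_precision_score(labels, scores))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (ties counted at half weight)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels, "ROC-AUC")
    return float(_skm.roc_auc_score(labels, scores))


def f1_accuracy(pred_labels, labels) -> tuple[float, float]:
    """F1 (harmonic mean of precision and recall) and plain accuracy."""
    pred = np.asarray(pred_labels, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if pred.shape != labels.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {labels.shape}")
    if pred.sum() == 0 and labels.sum() > 0:
        warnings.warn("no positive predictions while positives exist; F1 = 0")
    f1 = float(_skm.f1_score(labels, pred, zero_division=0))
    acc = float(_skm.accuracy_score(labels, pred))
    return f1, acc


@dataclass
class SplitSpec:
    split_date: _dt.date
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0,1)")


def temporal_split(trials: list[TrialRecord], spec: SplitSpec):
    """(train, validation, test) split on the calendar.

    Train pool: trials completing before the split date; test: trials
    starting after it; validation is a seeded random fraction of the train
    pool.  Trials straddling the date satisfy neither condition and are
    dropped (count logged).
    """
    for t in trials:
        if t.start_date is None or t.completion_date is None:
            raise ValueError(f"trial {t.trial_id} is undated")
    pool = [t for t in trials if t.completion_date < spec.split_date]
    test = [t for t in trials if t.start_date > spec.split_date]
    dropped = len(trials) - len(pool) - len(test)
    if dropped:
        log.info("temporal split dropped %d trials straddling %s",
                 dropped, spec.split_date)
    if not test:
        warnings.warn("temporal split produced an empty test set")
    rng = np.random.default_rng(spec.seed)
    n_val = int(round(spec.validation_fraction * len(pool)))
    val_idx = set(rng.choice(len(pool), size=n_val, replace=False)) if n_val else set()
    train = [t for i, t in enumerate(pool) if i not in val_idx]
    validation = [t for i, t in enumerate(pool) if i in val_idx]
    return train, validation, test


_METRIC_FNS = {
    "pr_auc": pr_auc,
    "roc_auc": roc_auc,
    "f1": lambda s, y: f1_accuracy((np.asarray(s) >= 0.5).astype(int), y)[0],
    "accuracy": lambda s, y: f1_accuracy((np.asarray(s) >= 0.5).astype(int), y)[1],
}


def bootstrap_pvalue(scores_a, scores_b, labels, metric: str = "pr_auc",
                     n_boot: int = 2000, seed: int = 0) -> float:
    """Paired one-sided bootstrap p-value for metric(b) > metric(a).

    Resamples evaluation indices with replacement; the p-value is the
    fraction of replicates (plus-one corrected) where method b fails to
    beat method a.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores_a, scores_b and labels must be paired")
    fn = _METRIC_FNS[metric]
    rng = np.random.default_rng(seed)
    worse = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(0, len(y), size=len(y))
        if len(np.unique(y[idx])) < 2:
            continue  # metric undefined on a single-class resample
        done += 1
        if fn(b[idx], y[idx]) <= fn(a[idx], y[idx]):
            worse += 1
    return (worse + 1) / (n_boot + 1)


def lambda_sweep(samples: list[ScoredSample], grid=None):
    """(lam, selective accuracy, fraction kept) along a threshold grid.

    Defaults to the observed confidences plus the 0/1 sentinels.  Fraction
    kept is non-increasing in lam by construction; a kept set of size zero
    reports the accuracy as NaN.
    """
    conf = np.array([s.confidence for s in samples])
    correct = np.array([s.pred_label == s.true_label for s in samples])
    if grid is None:
        grid = np.unique(np.concatenate([[0.0, 1.0], conf]))
    rows = []
    prev_kept = None
    for lam in np.asarray(grid, dtype=float):
        kept = conf >= lam
        frac = kept.mean()
        acc = float(correct[kept].mean()) if kept.any() else float("nan")
        if prev_kept is not None and frac > prev_kept + 1e-12:
            raise AssertionError("fraction kept increased along the grid")
        prev_kept = frac
        rows.append((float(lam), acc, float(frac)))
    return rows


def relative_improvement(base: float, improved: float) -> float:
    """Percentage change 100 * (improved - base) / base, to two decimals."""
    if base <= 0:
        raise ValueError(f"base metric must be positive, got {base}")
    return round(100.0 * (improved - base) / base, 2)


@dataclass
class MetricsReport:
    pr_auc: float
    roc_auc: float
    f1: float
    accuracy: float
    retain_rate: float
    n_eval: int
    bootstrap_sd: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def metrics_report(scores, labels, kept=None, n_boot: int = 200,
                   seed: int = 0) -> MetricsReport:
    """All four metrics (on the kept subset when a threshold is active)
    with bootstrap standard deviations."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if kept is None:
        kept = np.ones(len(scores), dtype=bool)
    else:
        kept = np.asarray(kept, dtype=bool)
    retain = float(kept.mean()) if len(kept) else 0.0
    s, y = scores[kept], labels[kept]
    pred = (s >= 0.5).astype(int)
    f1, acc = f1_accuracy(pred, y)
    report = MetricsReport(pr_auc=pr_auc(s, y), roc_auc=roc_auc(s, y),
                           f1=f1, accuracy=acc, retain_rate=retain,
                           n_eval=int(kept.sum()), bootstrap_sd={})
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {m: [] for m in _METRIC_FNS}
    done = 0
    while done < n_boot:
        idx = rng.integers(0, len(y), size=len(y))
        if len(np.unique(y[idx])) < 2:
            continue
        done += 1
        for m, fn in _METRIC_FNS.items():
            draws[m].append(fn(s[idx], y[idx]))
    report.bootstrap_sd = {m: float(np.std(v)) for m, v in draws.items()}
    return report
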