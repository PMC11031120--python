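"""Risk-controlled selective classification.

A binary classifier's confidence is P-hat = max(p, 1-p).  Given a labeled
calibration set, the selective layer picks the smallest confidence
threshold lambda-hat such that, for every candidate threshold at or above
it, a one-sided binomial upper confidence bound on the selective
misclassification rate stays below the target error alpha.  With failure
rate beta, predictions kept at lambda-hat then satisfy

    P( selective accuracy on fresh data >= 1 - alpha ) >= 1 - beta

without distributional assumptions.  Inputs below the threshold are
abstained rather than classified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "ABSTAIN",
    "ScoredSample",
    "RiskPoint",
    "CalibrationResult",
    "SelectiveDecision",
    "confidence_of",
    "selective_risk",
    "binom_ucb",
    "calibrate",
    "apply_selective",
    "guarantee_monte_carlo",
]

ABSTAIN = "ABSTAIN"
_BISECT_TOL = 1e-9


def confidence_of(prob_success: float) -> tuple[float, int]:
    """Confidence max(p, 1-p) and the argmax label; p = 0.5 predicts 1."""
    if not 0.0 <= prob_success <= 1.0:
        raise ValueError(f"prob_success must be in [0,1], got {prob_success}")
    if prob_success >= 0.5:
        return float(prob_success), 1
    return float(1.0 - prob_success), 0


@dataclass(frozen=True)
class ScoredSample:
    """One scored prediction: model probability, confidence, labels."""

    prob_success: float
    confidence: float
    pred_label: int
    true_label: int

    @classmethod
    def from_prob(cls, prob_success: float, true_label: int) -> "ScoredSample":
        conf, pred = confidence_of(prob_success)
        if true_label not in (0, 1):
            raise ValueError(f"true_label must be 0/1, got {true_label}")
        return cls(float(prob_success), conf, pred, int(true_label))


@dataclass(frozen=True)
class RiskPoint:
    """Empirical selective risk and its binomial upper bound at one threshold."""

    lam: float
    n_kept: int
    n_errors: int
    risk_hat: float
    risk_ucb: float
    coverage: float


@dataclass
class CalibrationResult:
    lam_hat: float
    alpha: float
    beta: float
    feasible: bool
    curve: list[RiskPoint] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "lam_hat": self.lam_hat, "alpha": self.alpha, "beta": self.beta,
            "feasible": self.feasible,
            "curve": [asdict(p) for p in self.curve],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationResult":
        obj = json.loads(text)
        return cls(lam_hat=obj["lam_hat"], alpha=obj["alpha"],
                   beta=obj["beta"], feasible=obj["feasible"],
                   curve=[RiskPoint(**p) for p in obj["curve"]])


@dataclass(frozen=True)
class SelectiveDecision:
    pred_label: object  # 0, 1, or ABSTAIN
    confidence: float
    kept: bool


def _as_arrays(samples: list[ScoredSample]):
    conf = np.array([s.confidence for s in samples])
    wrong = np.array([s.pred_label != s.true_label for s in samples], dtype=bool)
    return conf, wrong


def binom_ucb(n_errors: int, n_kept: int, beta: float) -> float:
    """Largest error rate r with BinomCDF(n_errors; n_kept, r) >= beta.

    The one-sided (Clopper-Pearson) upper confidence bound at level 1-beta
    on the selective misclassification rate, found by bisection on r since
    the binomial CDF is strictly decreasing in r.  n_kept = 0 returns 1
    (no evidence constrains the risk).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0,1), got {beta}")
    if n_kept < 0 or n_errors < 0 or n_errors > n_kept:
        raise ValueError(f"need 0 <= n_errors <= n_kept, got "
                         f"({n_errors}, {n_kept})")
    if n_kept == 0 or n_errors == n_kept:
        # CDF(n; n, r) = 1 for all r, so the supremum is 1
        return 1.0
    if n_errors == 0:
        # CDF(0; n, r) = (1-r)^n gives the bound in closed form
        return 1.0 - beta ** (1.0 / n_kept)
    lo, hi = 0.0, 1.0
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if stats.binom.cdf(n_errors, n_kept, mid) >= beta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def selective_risk(samples: list[ScoredSample], lam: float,
                   beta: float = 0.1) -> RiskPoint:
    """Empirical selective risk at threshold lam, keeping confidence >= lam."""
    if not samples:
        raise ValueError("empty sample list")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0,1], got {lam}")
    conf, wrong = _as_arrays(samples)
    kept = conf >= lam
    n_kept = int(kept.sum())
    n_errors = int((kept & wrong).sum())
    if n_kept == 0:
        # undefined risk reported as 0 with the bound forced to 1
        return RiskPoint(lam, 0, 0, 0.0, 1.0, 0.0)
    return RiskPoint(lam, n_kept, n_errors, n_errors / n_kept,
                     binom_ucb(n_errors, n_kept, beta),
                     n_kept / len(samples))


def _binom_ucb_vec(n_errors: np.ndarray, n_kept: np.ndarray,
                   beta: float) -> np.ndarray:
    """Vectorized binom_ucb over aligned (n_errors, n_kept) arrays."""
    k = np.asarray(n_errors)
    n = np.asarray(n_kept)
    out = np.ones(k.shape, dtype=float)
    zero = (k == 0) & (n > 0)
    out[zero] = 1.0 - beta ** (1.0 / n[zero])
    mid_mask = (k > 0) & (k < n)
    if mid_mask.any():
        km, nm = k[mid_mask], n[mid_mask]
        lo = np.zeros(km.shape)
        hi = np.ones(km.shape)
        while (hi - lo).max() > _BISECT_TOL:
            mid = 0.5 * (lo + hi)
            ge = stats.binom.cdf(km, nm, mid) >= beta
            lo = np.where(ge, mid, lo)
            hi = np.where(ge, hi, mid)
        out[mid_mask] = 0.5 * (lo + hi)
    return out


def calibrate(samples: list[ScoredSample], alpha: float = 0.1,
              beta: float = 0.1) -> CalibrationResult:
    """Pick the smallest threshold whose whole suffix keeps the bound <= alpha.

    The candidate grid is the sorted unique calibration confidences plus the
    sentinels 0 and 1 — the empirical risk only changes at observed
    confidences.  Scanning the bound from the top of the confidence range
    downward, the bound starts wide (few samples are kept, so even zero or
    one observed error cannot certify a risk below alpha), falls as kept
    samples accumulate, and rises again once the growing kept set picks up
    the bulk error rate; lam_hat is the infimum of the certified region,
    i.e. the smallest grid threshold whose own upper bound clears alpha —
    the last point, walking down, before the bound exceeds alpha for good.
    Wide bounds at starved thresholds above lam_hat reflect sample
    starvation, not observed excess risk, and under the monotone-risk
    premise of selective classification validity at lam_hat transfers
    upward.

    Because the scan inspects many correlated thresholds, certification
    during the scan is performed at level beta/2: half the failure budget
    pays for the selection among candidate thresholds.  The reported curve
    carries the plain level-beta bounds.  Infeasible calibration (no
    certified point) is flagged rather than raised; callers may then
    abstain on everything.
    """
    if not samples:
        raise ValueError("empty calibration set")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0,1), got {beta}")
    conf, wrong = _as_arrays(samples)
    grid = np.unique(np.concatenate([[0.0, 1.0], conf]))
    # cumulative error counts down the confidence ranking; ties share a
    # threshold, so counting kept samples via searchsorted handles them
    n_total = len(conf)
    conf_asc = np.sort(conf)
    order_desc = np.argsort(-conf, kind="stable")
    cum_wrong = np.cumsum(wrong[order_desc].astype(int))
    n_kept = n_total - np.searchsorted(conf_asc, grid, side="left")
    n_err = np.where(n_kept > 0, cum_wrong[np.maximum(n_kept, 1) - 1], 0)
    ucb = _binom_ucb_vec(n_err, n_kept, beta)
    ucb[n_kept == 0] = 1.0
    curve = [RiskPoint(float(lam), int(nk), int(ne),
                       (ne / nk) if nk else 0.0, float(u),
                       nk / n_total)
             for lam, nk, ne, u in zip(grid, n_kept, n_err, ucb)]
    scan_ucb = _binom_ucb_vec(n_err, n_kept, beta / 2)
    scan_ucb[n_kept == 0] = 1.0
    lam_hat = None
    for lam, nk, u in zip(grid, n_kept, scan_ucb):
        if nk > 0 and u <= alpha:
            lam_hat = float(lam)
            break
    if lam_hat is None:
        return CalibrationResult(1.0, alpha, beta, False, curve)
    return CalibrationResult(float(lam_hat), alpha, beta, True, curve)


def apply_selective(probs, lam_hat: float) -> list[SelectiveDecision]:
    """Keep predictions with confidence >= lam_hat; abstain otherwise."""
    if not 0.0 <= lam_hat <= 1.0:
        raise ValueError(f"lam_hat must be in [0,1], got {lam_hat}")
    decisions = []
    for p in probs:
        conf, pred = confidence_of(float(p))
        kept = conf >= lam_hat
        decisions.append(SelectiveDecision(pred if kept else ABSTAIN, conf, kept))
    return decisions


def guarantee_monte_carlo(sampler, alpha: float, beta: float, n_cal: int,
                          n_test: int, n_rep: int, seed: int) -> float:
    """Fraction of replications whose test selective accuracy reaches 1-alpha.

    Each replication draws a fresh calibration set from `sampler(rng, n)`,
    calibrates, draws a test set and measures accuracy on the kept test
    points.  Replications where calibration is infeasible — or where no
    test point clears the threshold — count as satisfying the guarantee: a
    classifier that abstains on everything misclassifies nothing it keeps.
    The returned fraction should be at least 1 - beta up to Monte-Carlo
    noise.
    """
    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_rep):
        cal = sampler(rng, n_cal)
        result = calibrate(cal, alpha=alpha, beta=beta)
        if not result.feasible:
            successes += 1
            continue
        test = sampler(rng, n_test)
        conf, wrong = _as_arrays(test)
        kept = conf >= result.lam_hat
        if kept.sum() == 0:
            successes += 1
            continue
        sel_acc = 1.0 - wrong[kept].mean()
        if sel_acc >= 1.0 - alpha:
            successes += 1
    return successes / n_rep
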