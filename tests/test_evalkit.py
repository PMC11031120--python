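"""Metrics, temporal split, bootstrap significance and the lambda sweep."""

import datetime as dt
import itertools

import numpy as np
import pytest

from trialselect import evalkit
from trialselect.evalkit import (pr_auc, roc_auc, f1_accuracy, temporal_split,
                                 bootstrap_pvalue, lambda_sweep,
                                 relative_improvement, SplitSpec,
                                 metrics_report)
from trialselect.riskcal import ScoredSample
from trialselect.synthgen import make_scored_sampler


def brute_force_pr_auc(scores, labels):
    """Step-curve area: sum over distinct thresholds of dRecall x Precision."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def pair_count_roc_auc(scores, labels):
    """Mann-Whitney: P(score_pos > score_neg) + P(tie)/2 over all pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRankMetrics:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_pr_auc_small_example_against_enumeration(self):
        scores, labels = [0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]
        assert pr_auc(scores, labels) == pytest.approx(
            brute_force_pr_auc(scores, labels), abs=1e-12)

    def test_oracle_agreement_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 31))
            scores = np.round(rng.uniform(size=n), 2)  # force ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert pr_auc(scores, labels) == pytest.approx(
                brute_force_pr_auc(scores, labels), abs=1e-9)
            assert roc_auc(scores, labels) == pytest.approx(
                pair_count_roc_auc(scores, labels), abs=1e-9)

    def test_permutation_invariance(self, rng):
        scores = rng.uniform(size=20)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        perm = rng.permutation(20)
        assert pr_auc(scores, labels) == pytest.approx(
            pr_auc(scores[perm], labels[perm]))

    def test_roc_symmetry_under_label_flip(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(-scores, 1 - labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.9], [1, 1])
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [0, 0])


class TestF1Accuracy:
    def test_all_correct(self):
        assert f1_accuracy([1, 0, 1], [1, 0, 1]) == (1.0, 1.0)

    def test_balanced_confusion(self):
        # TP=1 FP=1 FN=1 TN=1
        f1, acc = f1_accuracy([1, 1, 0, 0], [1, 0, 1, 0])
        assert f1 == pytest.approx(0.5)
        assert acc == pytest.approx(0.5)

    def test_no_positive_predictions(self):
        with pytest.warns(UserWarning):
            f1, acc = f1_accuracy([0, 0, 0], [1, 1, 0])
        assert f1 == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            f1_accuracy([1, 0], [1])


class TestTemporalSplit:
    def _dated(self, trials):
        return [t for t in trials
                if t.start_date is not None and t.completion_date is not None]

    def test_partition_respects_dates(self, small_dataset):
        config, trials, _, _ = small_dataset
        spec = SplitSpec(config.split_date, 0.15, seed=0)
        train, val, test = temporal_split(trials, spec)
        for t in train + val:
            assert t.completion_date < config.split_date
        for t in test:
            assert t.start_date > config.split_date

    def test_straddlers_dropped(self, small_dataset):
        config, trials, _, _ = small_dataset
        spec = SplitSpec(config.split_date, 0.15, seed=0)
        train, val, test = temporal_split(trials, spec)
        straddlers = [t for t in trials
                      if t.start_date <= config.split_date
                      and t.completion_date >= config.split_date]
        assert straddlers  # the generator straddles by construction
        kept_ids = {t.trial_id for t in train + val + test}
        assert all(t.trial_id not in kept_ids for t in straddlers)

    def test_validation_fraction_and_reproducibility(self, small_dataset):
        config, trials, _, _ = small_dataset
        spec = SplitSpec(config.split_date, 0.2, seed=5)
        tr1, va1, te1 = temporal_split(trials, spec)
        tr2, va2, te2 = temporal_split(trials, spec)
        assert [t.trial_id for t in va1] == [t.trial_id for t in va2]
        pool = len(tr1) + len(va1)
        assert len(va1) == round(0.2 * pool)

    def test_all_before_split_warns_empty_test(self, small_dataset):
        _, trials, _, _ = small_dataset
        spec = SplitSpec(dt.date(2050, 1, 1), 0.1, seed=0)
        with pytest.warns(UserWarning):
            _, _, test = temporal_split(trials, spec)
        assert test == []

    def test_undated_trial_rejected(self, small_dataset):
        _, trials, _, _ = small_dataset
        from trialselect.hintnet.records import TrialRecord
        bad = TrialRecord("T-undated", ["CCO"], ["R00.0.0.0"])
        with pytest.raises(ValueError, match="T-undated"):
            temporal_split(trials + [bad],
                           SplitSpec(dt.date(2013, 8, 7), 0.1))


class TestBootstrap:
    def test_identical_scores_not_significant(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.uniform(size=40)
        p = bootstrap_pvalue(s, s, y, "roc_auc", n_boot=200, seed=0)
        assert p > 0.9

    def test_dominating_method_hits_floor(self, rng):
        y = np.array([0, 1] * 20)
        a = rng.uniform(0.4, 0.6, size=40)
        b = y * 0.9 + 0.05  # perfect scores
        n_boot = 200
        p = bootstrap_pvalue(a, b, y, "roc_auc", n_boot=n_boot, seed=0)
        assert p == pytest.approx(1 / (n_boot + 1))

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_pvalue([0.1], [0.2, 0.3], [0, 1])


class TestLambdaSweep:
    def test_lambda_zero_reproduces_full_accuracy(self, rng):
        samples = make_scored_sampler()(rng, 200)
        correct = np.array([s.pred_label == s.true_label for s in samples])
        rows = lambda_sweep(samples)
        lam0 = [r for r in rows if r[0] == 0.0][0]
        assert lam0[1] == pytest.approx(correct.mean())
        assert lam0[2] == 1.0

    def test_fraction_kept_non_increasing(self, rng):
        samples = make_scored_sampler()(rng, 300)
        rows = lambda_sweep(samples)
        fracs = [r[2] for r in rows]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_selective_accuracy_beats_full_coverage_at_half_kept(self, rng):
        """With confidence-correlated errors, halving coverage must raise
        accuracy on the kept subset."""
        samples = make_scored_sampler(miscalibration=0.05)(rng, 2000)
        rows = lambda_sweep(samples)
        full_acc = rows[0][1]
        near_half = min(rows, key=lambda r: abs(r[2] - 0.5))
        assert 0.4 < near_half[2] < 0.6
        assert near_half[1] > full_acc

    def test_kept_metrics_match_physical_deletion(self, rng):
        samples = make_scored_sampler()(rng, 400)
        probs = np.array([s.prob_success for s in samples])
        labels = np.array([s.true_label for s in samples])
        conf = np.array([s.confidence for s in samples])
        lam = np.median(conf)
        kept = conf >= lam
        rep_masked = metrics_report(probs, labels, kept=kept, n_boot=20, seed=0)
        rep_deleted = metrics_report(probs[kept], labels[kept], n_boot=20,
                                     seed=0)
        assert rep_masked.pr_auc == pytest.approx(rep_deleted.pr_auc)
        assert rep_masked.roc_auc == pytest.approx(rep_deleted.roc_auc)
        assert rep_masked.accuracy == pytest.approx(rep_deleted.accuracy)


class TestRelativeImprovement:
    @pytest.mark.parametrize("base, improved, expected", [
        (0.5765, 0.7631, 32.37),   # PR-AUC, early-phase cohort
        (0.7965, 0.9022, 13.27),   # PR-AUC, late-phase cohort
        (0.25, 0.25, 0.0),
    ])
    def test_percentage_arithmetic(self, base, improved, expected):
        assert relative_improvement(base, improved) == pytest.approx(expected)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(0.0, 0.5)
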