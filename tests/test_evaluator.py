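"""Metric implementations against brute-force and reference oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snapqsar.errors import DegenerateLabelsError
from snapqsar.evaluator import (aggregate_molecule, confusion_metrics,
                                evaluate_scores, paper_roc_auc, pr_auc,
                                roc_auc, youden_cutoff)


# ---------------------------------------------------------------------------
# oracles

def brute_youden(scores, labels):
    """Exhaustive search over every observed threshold, smallest-theta ties."""
    best_theta, best_j = None, -np.inf
    for theta in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if s >= theta and y == 1)
        fn = sum(1 for s, y in zip(scores, labels) if s < theta and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < theta and y == 0)
        fp = sum(1 for s, y in zip(scores, labels) if s >= theta and y == 0)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j > best_j + 1e-15:
            best_j, best_theta = j, theta
    return best_theta


def brute_roc_auc(scores, labels):
    """Pairwise U-statistic: P(active > inactive) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def brute_pr_auc(scores, labels):
    """Step integration of the recall/precision curve over thresholds."""
    n_pos = sum(labels)
    auc, prev_r = 0.0, 0.0
    for theta in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= theta and y == 1)
        pred = sum(1 for s in scores if s >= theta)
        auc += (tp / n_pos - prev_r) * (tp / pred)
        prev_r = tp / n_pos
    return auc


def random_instance(rng, n_max=50, tie_prob=0.3):
    n = rng.integers(4, n_max + 1)
    labels = np.zeros(n, dtype=int)
    labels[: rng.integers(1, n)] = 1
    rng.shuffle(labels)
    if rng.random() < tie_prob:  # discrete scores force ties
        scores = rng.integers(0, 5, n) / 4.0
    else:
        scores = rng.random(n)
    return scores.tolist(), labels.tolist()


# ---------------------------------------------------------------------------
# aggregation

@pytest.mark.parametrize("probs, expected", [
    ([0.2, 0.8, 0.5], 0.5),
    ([0.2, 0.4, 0.6, 0.8], 0.5),
    ([0.9], 0.9),
])
def test_median_aggregation(probs, expected):
    assert aggregate_molecule(probs) == pytest.approx(expected)


def test_aggregation_rejects_empty():
    with pytest.raises(ValueError):
        aggregate_molecule([])


# ---------------------------------------------------------------------------
# Youden cutoff

def test_youden_perfect_separation():
    theta = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert theta == pytest.approx(0.8)


def test_youden_single_class_raises():
    with pytest.raises(DegenerateLabelsError):
        youden_cutoff([0.1, 0.9], [1, 1])


def test_youden_matches_exhaustive_oracle(rng):
    for _ in range(500):
        scores, labels = random_instance(rng)
        if len(set(labels)) < 2:
            continue
        assert youden_cutoff(scores, labels) == pytest.approx(
            brute_youden(scores, labels))


# ---------------------------------------------------------------------------
# confusion metrics

def test_perfect_classifier_metrics():
    r = confusion_metrics([0.9] * 5 + [0.1] * 5, [1] * 5 + [0] * 5, 0.5)
    assert (r.acc, r.bac, r.f, r.mcc) == (1.0, 1.0, 1.0, 1.0)


def test_metrics_printed_formulas():
    # tp=2 fp=1 tn=3 fn=0 under theta=0.5
    scores = [0.9, 0.8, 0.7, 0.1, 0.2, 0.3]
    labels = [1, 1, 0, 0, 0, 0]
    r = confusion_metrics(scores, labels, 0.5)
    assert (r.confusion.tp, r.confusion.fp, r.confusion.tn, r.confusion.fn) \
        == (2, 1, 3, 0)
    assert r.acc == pytest.approx(5 / 6)
    assert r.precision == pytest.approx(2 / 3)
    assert r.recall == 1.0
    assert r.f == pytest.approx(0.8)
    # MCC by direct substitution: (2*3-1*0)/sqrt(3*2*4*3)
    assert r.mcc == pytest.approx(6 / np.sqrt(72))


def test_mcc_degenerate_denominator_is_zero():
    r = confusion_metrics([0.1] * 10, [1] * 5 + [0] * 5, 0.5)
    assert (r.confusion.tp, r.confusion.fp) == (0, 0)
    assert r.mcc == 0.0


def test_metrics_match_sklearn_on_random_matrices(rng):
    from sklearn.metrics import (balanced_accuracy_score, f1_score,
                                 matthews_corrcoef, precision_score)

    checked = 0
    while checked < 1000:
        scores, labels = random_instance(rng, n_max=30)
        theta = 0.5
        pred = [int(s >= theta) for s in scores]
        if len(set(pred)) < 2 or len(set(labels)) < 2:
            continue
        r = confusion_metrics(scores, labels, theta)
        assert r.bac == pytest.approx(balanced_accuracy_score(labels, pred))
        assert r.f == pytest.approx(f1_score(labels, pred))
        assert r.mcc == pytest.approx(matthews_corrcoef(labels, pred))
        assert r.precision == pytest.approx(precision_score(labels, pred))
        checked += 1


def test_bac_identity_holds_for_every_report(rng):
    for _ in range(50):
        scores, labels = random_instance(rng)
        if len(set(labels)) < 2:
            continue
        r = evaluate_scores(scores, labels)
        assert r.bac == (r.sensitivity + r.specificity) / 2


# ---------------------------------------------------------------------------
# ROC AUC

def test_roc_auc_perfect_and_antiperfect():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0]) == 0.0


def test_roc_auc_matches_u_statistic_oracle(rng):
    for _ in range(500):
        scores, labels = random_instance(rng)
        if len(set(labels)) < 2:
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            brute_roc_auc(scores, labels), abs=1e-12)


def test_roc_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(100):
        scores, labels = random_instance(rng)
        if len(set(labels)) < 2:
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=30),
       st.integers(1, 2**30))
def test_roc_auc_complement_and_monotone_invariance(scores, seed):
    rng = np.random.default_rng(seed)
    labels = np.zeros(len(scores), dtype=int)
    labels[: rng.integers(1, len(scores))] = 1
    rng.shuffle(labels)
    scores = np.round(scores, 3)
    if len(np.unique(scores)) < len(scores):
        return  # complement identity stated for tie-free scores
    a = roc_auc(scores, labels)
    assert a + roc_auc(1 - np.asarray(scores), labels) == pytest.approx(1.0)
    # strictly increasing transform leaves ranks unchanged
    assert roc_auc(np.exp(3 * np.asarray(scores)), labels) == pytest.approx(a)


# ---------------------------------------------------------------------------
# PR AUC

def test_pr_auc_trivial_cases():
    assert pr_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    # constant scores: single-point curve collapses to prevalence
    assert pr_auc([0.5] * 8, [1, 1, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.25)


def test_pr_auc_matches_step_integration_oracle(rng):
    for _ in range(500):
        scores, labels = random_instance(rng)
        if len(set(labels)) < 2:
            continue
        assert pr_auc(scores, labels) == pytest.approx(
            brute_pr_auc(scores, labels), abs=1e-9)


def test_pr_auc_matches_sklearn_average_precision(rng):
    from sklearn.metrics import average_precision_score

    for _ in range(100):
        scores, labels = random_instance(rng)
        if len(set(labels)) < 2:
            continue
        assert pr_auc(scores, labels) == pytest.approx(
            average_precision_score(labels, scores))


# ---------------------------------------------------------------------------
# threshold-weighted AUC approximation

def test_paper_auc_separated_data():
    est, inter = paper_roc_auc([1, 1, 0, 0], [1, 1, 0, 0])
    assert 0.0 <= est <= 1.0
    assert est >= roc_auc([1, 1, 0, 0], [1, 1, 0, 0]) - 0.1
    assert inter.np_true == 2
    assert inter.n_thresholds == 2
    assert all(0.0 <= p <= 1.0 for p in inter.prec_t)


def test_paper_auc_translation_invariance(rng):
    for _ in range(50):
        scores, labels = random_instance(rng, n_max=20)
        if len(set(labels)) < 2:
            continue
        est, _ = paper_roc_auc(scores, labels)
        shifted, _ = paper_roc_auc([s + 2.5 for s in scores], labels)
        assert est == pytest.approx(shifted)


def test_paper_auc_single_class_raises():
    with pytest.raises(DegenerateLabelsError):
        paper_roc_auc([0.1, 0.9], [0, 0])


# ---------------------------------------------------------------------------
# evaluate_scores

def test_constant_scorer_has_chance_bac():
    r = evaluate_scores([0.5] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    assert r.bac == pytest.approx(0.5)


def test_evaluate_scores_deterministic():
    scores = [0.8, 0.3, 0.6, 0.1, 0.9, 0.2]
    labels = [1, 0, 1, 0, 1, 0]
    assert evaluate_scores(scores, labels) == evaluate_scores(scores, labels)
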