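"""Per-molecule aggregation, Youden-index cutoff, and classification metrics.

The classifier scores every snapshot image; a molecule's representative
score is the *median* over its images.  The decision cutoff theta is chosen
by maximising Youden's J statistic (sensitivity + specificity - 1) over the
observed molecule scores, ties broken toward the smallest cutoff; a molecule
is called active when its score is >= theta.  From the resulting confusion
matrix the report carries sensitivity, specificity, balanced accuracy
BAC = (sensitivity + specificity) / 2, accuracy, precision, recall,
F = 2 * recall * precision / (recall + precision), and Matthews' correlation
coefficient (0 by convention when its denominator vanishes), together with
the rank-based (Mann-Whitney) ROC AUC, the step-integrated precision-recall
AUC, and the mean cross-entropy loss of the aggregated scores.

``paper_roc_auc`` additionally provides a threshold-weighted, precision-
interpolated approximation of the ROC AUC (weights are central differences
of the precision profile over the score thresholds); it is kept separate
from the rank-based estimator because the two differ numerically except on
well-separated score distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateLabelsError
from .render import SnapshotSet, load_snapshot
from .trainer import TrainedModel, cross_entropy, preprocess_images


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    theta: float
    sensitivity: float
    specificity: float
    bac: float
    acc: float
    precision: float
    recall: float
    f: float
    mcc: float
    roc_auc: float
    pr_auc: float
    loss: float
    confusion: ConfusionMatrix

    def __post_init__(self) -> None:
        assert abs(self.bac - (self.sensitivity + self.specificity) / 2) < 1e-12
        assert -1.0 - 1e-12 <= self.mcc <= 1.0 + 1e-12

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = asdict(self.confusion)
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        d = self.to_dict()
        conf = d.pop("confusion")
        d.update(conf)
        lines = [f"{k}\t{v}" for k, v in d.items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PaperAucIntermediates:
    """Inspection record for the threshold-weighted AUC approximation."""

    np_true: int
    n_thresholds: int
    thresholds: list[float]
    prec_t: list[float]          # extended profile, conventions applied
    w_t: list[float]
    p_j: list[float]
    c_i: list[int]
    f_j: list[float]


def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(
        [1 if lab in (1, True, "active") else 0 for lab in labels], dtype=int)
    return arr


def _require_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise DegenerateLabelsError("both classes must be present")


def aggregate_molecule(image_probs: Sequence[float]) -> float:
    """Median of per-image probabilities (mean of middle two for even counts)."""
    probs = np.asarray(image_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("cannot aggregate an empty probability list")
    return float(np.median(probs))


def youden_cutoff(scores: Sequence[float], labels: Sequence) -> float:
    """Cutoff maximising Youden's J over the observed scores.

    Candidates are the observed score values (rule: active iff score >=
    theta); ties go to the smallest cutoff.
    """
    y = _as_binary(labels)
    _require_both_classes(y)
    s = np.asarray(scores, dtype=float)
    best_theta, best_j = None, -np.inf
    for theta in np.unique(s):  # unique() is sorted ascending
        pred = s >= theta
        tp = int(np.sum(pred & (y == 1)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        fp = int(np.sum(pred & (y == 0)))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j, best_theta = j, float(theta)
    return best_theta


def confusion_metrics(scores: Sequence[float], labels: Sequence,
                      theta: float) -> MetricsReport:
    """Confusion-matrix metrics at cutoff theta (AUCs and loss left at nan/0).

    All ratio metrics with a zero denominator are defined as 0, including
    the MCC convention.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= theta
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))

    def ratio(num: float, den: float) -> float:
        return num / den if den else 0.0

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    rec = sens
    f = ratio(2 * rec * prec, rec + prec)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0
    return MetricsReport(
        theta=float(theta),
        sensitivity=sens,
        specificity=spec,
        bac=(sens + spec) / 2.0,
        acc=ratio(tp + tn, tp + fp + tn + fn),
        precision=prec,
        recall=rec,
        f=f,
        mcc=float(mcc),
        roc_auc=float("nan"),
        pr_auc=float("nan"),
        loss=float("nan"),
        confusion=ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn),
    )


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties contribute 1/2."""
    y = _as_binary(labels)
    _require_both_classes(y)
    s = np.asarray(scores, dtype=float)
    # midranks via sorting; equivalent to the U statistic
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # midrank, 1-based
        i = j + 1
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Precision-recall AUC by step integration (average precision)."""
    y = _as_binary(labels)
    _require_both_classes(y)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    auc = 0.0
    prev_recall = 0.0
    for theta in np.unique(s)[::-1]:  # descending thresholds
        pred = s >= theta
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        auc += (recall - prev_recall) * precision
        prev_recall = recall
    return float(auc)


def paper_roc_auc(scores: Sequence[float],
                  labels: Sequence) -> tuple[float, PaperAucIntermediates]:
    """Threshold-weighted, precision-interpolated AUC approximation.

    Thresholds are the sorted unique scores (taken in descending order so
    that the precision profile is non-increasing for well-ranked data).
    With prec_t the precision at threshold t and the boundary conventions
    prec_0 = prec_1 and prec_T = 0, each threshold carries the central-
    difference weight W_t = (prec_{t-1} - prec_{t+1}) / 2 and each true
    point j accumulates f_j = sum of W_t over thresholds its score reaches;
    the estimate is the mean of f_j over the true points.  The weighted sum
    telescopes to the interpolated precision at each true point's own
    threshold, so the estimate is translation-invariant in the scores and
    equals 1 on perfectly separated data.
    """
    y = _as_binary(labels)
    _require_both_classes(y)
    s = np.asarray(scores, dtype=float)
    thresholds = np.unique(s)[::-1]  # descending
    t_count = len(thresholds)

    prec = np.zeros(t_count + 2)  # indices 0..T+1
    for t_idx, theta in enumerate(thresholds, start=1):
        covered = s >= theta
        prec[t_idx] = y[covered].sum() / covered.sum()
    prec[0] = prec[1]
    prec[t_count] = 0.0  # endpoint convention overrides the lowest threshold
    prec[t_count + 1] = 0.0

    w = np.array([(prec[t - 1] - prec[t + 1]) / 2.0
                  for t in range(1, t_count + 1)])

    pos_scores = s[y == 1]
    f_j = np.array([w[s_j >= thresholds].sum() for s_j in pos_scores])
    estimate = float(f_j.mean())
    inter = PaperAucIntermediates(
        np_true=int(y.sum()),
        n_thresholds=t_count,
        thresholds=[float(t) for t in thresholds],
        prec_t=[float(p) for p in prec],
        w_t=[float(x) for x in w],
        p_j=[float(x) for x in pos_scores],
        c_i=[int(c) for c in y],
        f_j=[float(x) for x in f_j],
    )
    return estimate, inter


def evaluate_scores(scores: Sequence[float], labels: Sequence,
                    theta: float | None = None) -> MetricsReport:
    """Full metrics from per-molecule scores; theta fit on these scores
    unless supplied (e.g. reusing a validation-set cutoff)."""
    y = _as_binary(labels)
    _require_both_classes(y)
    if theta is None:
        theta = youden_cutoff(scores, labels)
    report = confusion_metrics(scores, labels, theta)
    report.roc_auc = roc_auc(scores, labels)
    report.pr_auc = pr_auc(scores, labels)
    report.loss = cross_entropy(scores, y)
    return report


def molecule_scores(model: TrainedModel,
                    snapshot_sets: Sequence[SnapshotSet]) -> dict[str, float]:
    """Predict every image of every molecule and aggregate by median."""
    out: dict[str, float] = {}
    for sset in snapshot_sets:
        images = [load_snapshot(path) for _, path in sset.items]
        probs = model.predict_proba(preprocess_images(images, model.input_size))
        out[sset.molecule_id] = aggregate_molecule(probs)
    return out


def evaluate(model: TrainedModel, snapshot_sets: Sequence[SnapshotSet],
             labels: Mapping[str, str | int],
             partition_ids: Sequence[str] | None = None,
             theta: float | None = None) -> MetricsReport:
    """End-to-end evaluation of one partition.

    Pipeline: per-image prediction -> per-molecule median -> Youden cutoff
    on this partition's scores (unless ``theta`` is given) -> confusion
    metrics, rank AUC, PR AUC and mean cross-entropy loss.
    """
    if partition_ids is not None:
        wanted = set(partition_ids)
        snapshot_sets = [s for s in snapshot_sets if s.molecule_id in wanted]
    missing = [s.molecule_id for s in snapshot_sets if s.molecule_id not in labels]
    if missing:
        raise ValueError(f"molecules without labels: {missing[:5]}")
    scores_by_id = molecule_scores(model, snapshot_sets)
    mol_ids = sorted(scores_by_id)
    scores = [scores_by_id[m] for m in mol_ids]
    y = [labels[m] for m in mol_ids]
    return evaluate_scores(scores, y, theta=theta)
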