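"""Decision thresholds, the non-empty decision rule, and the metric suite.

Per-label decision thresholds are chosen on training scores by maximizing the
Matthews correlation coefficient (MCC), which is robust to the heavy class
imbalance of localization corpora.  At prediction time a label is assigned
when its score reaches its threshold; if no label does, the single label whose
score is closest to its threshold is assigned, so the decided set is never
empty and the mean predicted label count is always >= 1.

Metric conventions (documented because multi-label literature varies):

- accuracy is exact subset match between the decided and true label sets;
- the sample Jaccard index |intersection|/|union| defines the empty/empty
  case as 1 (unreachable under the fallback rule, but the metric is total);
- macro-F1 scores a label as 0 when it has neither positives nor predictions;
- AUC uses the rank (Mann-Whitney) formula with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "ThresholdSet",
    "MultiLabelPrediction",
    "MetricReport",
    "mcc",
    "fit_thresholds",
    "decide",
    "evaluate",
    "kl_divergence",
    "attention_signal_kl",
    "auc_per_label",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def _mcc_from_arrays(pred: np.ndarray, target: np.ndarray) -> float:
    tp = int(np.sum((pred == 1) & (target == 1)))
    fp = int(np.sum((pred == 1) & (target == 0)))
    tn = int(np.sum((pred == 0) & (target == 0)))
    fn = int(np.sum((pred == 0) & (target == 1)))
    return mcc(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))


@dataclass(frozen=True)
class ThresholdSet:
    """One decision threshold per label, fit on training data only."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        if self.tau.ndim != 1:
            raise ValueError("thresholds must form a 1-D vector")


def _fit_threshold_single(scores: np.ndarray, targets: np.ndarray) -> float:
    """MCC-maximizing cut for one label.

    Candidates are 0, 1, and the midpoints between consecutive sorted unique
    scores; the decision is ``score >= tau``.  Ties in MCC break toward the
    smallest threshold.
    """
    if targets.min() == targets.max():
        # Degenerate label: only one class present in training data.
        return 0.5
    uniq = np.unique(scores)
    candidates = np.concatenate(
        ([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0])
    )
    candidates = np.unique(candidates)
    best_tau = candidates[0]
    best_mcc = -np.inf
    for tau in candidates:
        value = _mcc_from_arrays((scores >= tau).astype(int), targets)
        if value > best_mcc + 1e-15:
            best_mcc = value
            best_tau = tau
    return float(best_tau)


def fit_thresholds(scores: np.ndarray, targets: np.ndarray) -> ThresholdSet:
    """Per-label MCC-optimal thresholds for an (n, C) score matrix."""
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if scores.shape != targets.shape or scores.ndim != 2:
        raise ValueError("scores and targets must both be (n, C)")
    if scores.shape[0] < 2:
        raise ValueError("need at least two samples to fit thresholds")
    tau = np.array(
        [
            _fit_threshold_single(scores[:, c], targets[:, c])
            for c in range(scores.shape[1])
        ]
    )
    return ThresholdSet(tau=tau)


@dataclass(frozen=True)
class MultiLabelPrediction:
    id: str
    scores: np.ndarray
    decided: np.ndarray
    fallback_used: bool

    def __post_init__(self) -> None:
        if self.decided.sum() < 1:
            raise ValueError("decided label set must be non-empty")


def decide(
    scores: np.ndarray, thresholds: ThresholdSet, ids: list[str] | None = None
) -> list[MultiLabelPrediction]:
    """Threshold scores into decided label sets with the closest-label fallback.

    A label is on when its score >= its threshold (inclusive).  When no label
    crosses, the label maximizing ``score - threshold`` is assigned alone
    (ties break to the lowest label index), so the output set is never empty.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    tau = thresholds.tau
    if scores.shape[1] != tau.shape[0]:
        raise ValueError(
            f"score dimension {scores.shape[1]} != threshold dimension {tau.shape[0]}"
        )
    if ids is None:
        ids = [str(i) for i in range(scores.shape[0])]
    out: list[MultiLabelPrediction] = []
    for i in range(scores.shape[0]):
        p = scores[i]
        dec = (p >= tau).astype(int)
        fallback = False
        if dec.sum() == 0:
            dec = np.zeros_like(dec)
            dec[int(np.argmax(p - tau))] = 1  # argmax takes lowest index on ties
            fallback = True
        out.append(
            MultiLabelPrediction(
                id=ids[i], scores=p.copy(), decided=dec, fallback_used=fallback
            )
        )
    return out


@dataclass
class MetricReport:
    exact_match_accuracy: float
    jaccard: float
    micro_f1: float
    macro_f1: float
    mcc_per_label: np.ndarray
    mean_predicted_labels: float
    auc_per_label: np.ndarray | None = None
    kl_stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    def as_dict(self, classes: list[str] | None = None) -> dict:
        d = {
            "exact_match_accuracy": self.exact_match_accuracy,
            "jaccard": self.jaccard,
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "mean_predicted_labels": self.mean_predicted_labels,
        }
        names = classes or [str(c) for c in range(len(self.mcc_per_label))]
        for name, value in zip(names, self.mcc_per_label):
            d[f"mcc_{name}"] = float(value)
        if self.auc_per_label is not None:
            for name, value in zip(names, self.auc_per_label):
                d[f"auc_{name}"] = float(value)
        for sig, (mean, sd, count) in self.kl_stats.items():
            d[f"kl_{sig}_mean"] = mean
            d[f"kl_{sig}_sd"] = sd
            d[f"kl_{sig}_n"] = count
        return d


def evaluate(
    decided: np.ndarray,
    truth: np.ndarray,
    scores: np.ndarray | None = None,
) -> MetricReport:
    """Full multi-label metric suite on (n, C) binary decision/truth matrices."""
    decided = np.asarray(decided, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if decided.shape != truth.shape or decided.ndim != 2:
        raise ValueError("decided and truth must both be (n, C)")
    n, C = decided.shape
    if n < 1:
        raise ValueError("need at least one sample")

    exact = float(np.mean(np.all(decided == truth, axis=1)))

    inter = np.sum((decided == 1) & (truth == 1), axis=1)
    union = np.sum((decided == 1) | (truth == 1), axis=1)
    per_sample = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    jac = float(np.mean(per_sample))

    micro = float(f1_score(truth, decided, average="micro", zero_division=0))
    macro = float(f1_score(truth, decided, average="macro", zero_division=0))

    mccs = np.array(
        [_mcc_from_arrays(decided[:, c], truth[:, c]) for c in range(C)]
    )
    mean_count = float(np.mean(decided.sum(axis=1)))

    aucs = None
    if scores is not None:
        aucs = auc_per_label(np.asarray(scores, dtype=float), truth)

    return MetricReport(
        exact_match_accuracy=exact,
        jaccard=jac,
        micro_f1=micro,
        macro_f1=macro,
        mcc_per_label=mccs,
        mean_predicted_labels=mean_count,
        auc_per_label=aucs,
    )


def kl_divergence(q: np.ndarray, a: np.ndarray) -> float:
    """KL(q || a) over positions, summed where q > 0."""
    q = np.asarray(q, dtype=float)
    a = np.asarray(a, dtype=float)
    support = q > 0
    return float(np.sum(q[support] * np.log(q[support] / a[support])))


def attention_signal_kl(weights: np.ndarray, mask: np.ndarray) -> float:
    """KL divergence between the uniform-over-annotation distribution q and
    the attention weights a: KL(q || a).

    Low values mean the attention concentrates on the annotated signal
    residues.  Undefined (ValueError) for an empty mask.
    """
    mask = np.asarray(mask, dtype=float)
    if mask.sum() == 0:
        raise ValueError("signal mask is empty; KL undefined")
    q = mask / mask.sum()
    return kl_divergence(q, np.asarray(weights, dtype=float))


def auc_per_label(scores: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-label ROC AUC; NaN where a label lacks one of the two classes."""
    C = scores.shape[1]
    out = np.full(C, np.nan)
    for c in range(C):
        y = targets[:, c]
        if y.min() == y.max():
            continue
        out[c] = roc_auc_score(y, scores[:, c])
    return out
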