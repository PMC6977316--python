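"""Tanimoto 1-NN benchmarking: metric panel, split protocol and
Y-randomization.

The evaluation protocol is ten repeats of a seeded, stratified 80/20
train/external split; within each repeat a tenfold cross-validation is run
on the training portion for protocol fidelity, and the headline output is
the average of the ten external-validation metric sets.  The classifier is
1-nearest-neighbor under Tanimoto similarity of binary fingerprints — it
has no tunable parameters, so performance reflects the descriptor alone.

Y-randomization refits the whole protocol on label-shuffled copies of the
data and summarizes the original model against the shuffled distribution
as Z-scores of MCC and accuracy; Z > 3 is read as significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD_UM = 10.0  # IC50 cutoff, µmol; active strictly below


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    undefined_ratios: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "f1": self.f1, "mcc": self.mcc}


@dataclass(frozen=True)
class SplitProtocol:
    """Repeated stratified 80/20 splitting with tenfold CV on the training
    portion.  ``cv_folds=0`` disables cross-validation (used to keep
    Y-randomization rounds cheap)."""

    train_fraction: float = 0.8
    repeats: int = 10
    cv_folds: int = 10
    seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class TaskResult:
    external: list[MetricSet]
    cv: list[Optional[MetricSet]]
    external_mean: MetricSet = field(init=False)

    def __post_init__(self):
        self.external_mean = _mean_metrics(self.external)

    def summary(self) -> dict:
        out = {"external_mean": self.external_mean.as_dict(),
               "n_repeats": len(self.external),
               "external_per_repeat": [m.as_dict() for m in self.external]}
        cv = [m for m in self.cv if m is not None]
        if cv:
            out["cv_mean"] = _mean_metrics(cv).as_dict()
        return out


@dataclass
class YRandResult:
    mcc_ori: float
    acc_ori: float
    mcc_rand_mean: float
    acc_rand_mean: float
    mcc_rand_sd: float
    acc_rand_sd: float
    z_mcc: float
    z_acc: float
    rounds: int
    degenerate: bool = False  # zero spread across random rounds

    def significant(self, threshold: float = 3.0) -> bool:
        return (not self.degenerate) and self.z_mcc > threshold

    def as_dict(self) -> dict:
        return {"mcc_ori": self.mcc_ori, "acc_ori": self.acc_ori,
                "mcc_rand_mean": self.mcc_rand_mean,
                "acc_rand_mean": self.acc_rand_mean,
                "mcc_rand_sd": self.mcc_rand_sd,
                "acc_rand_sd": self.acc_rand_sd,
                "z_mcc": self.z_mcc, "z_acc": self.z_acc,
                "rounds": self.rounds, "degenerate": self.degenerate}


def z_score(original: float, rand_mean: float, rand_sd: float) -> float:
    """Y-randomization Z: (metric_ori - mean_rand) / sd_rand."""
    if rand_sd <= 0:
        return float("nan")
    return (original - rand_mean) / rand_sd


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two equal-length binary
    vectors; two all-zero vectors score 0 by convention."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(queries: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarities, queries x train, vectorized."""
    q = np.asarray(queries, dtype=np.float32)
    t = np.asarray(train, dtype=np.float32)
    inter = q @ t.T
    union = q.sum(axis=1)[:, None] + t.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def one_nn_predict(train_bits: np.ndarray, train_labels: Sequence,
                   queries: np.ndarray) -> np.ndarray:
    """Label of the most Tanimoto-similar training item for each query.

    Ties are broken deterministically in favor of the earliest training
    item (stable input order); ties between different labels are logged.
    """
    train_bits = np.atleast_2d(train_bits)
    queries = np.atleast_2d(queries)
    if len(train_labels) == 0:
        raise ValueError("training set is empty")
    labels = np.asarray(train_labels)
    sim = tanimoto_matrix(queries, train_bits)
    best = np.argmax(sim, axis=1)  # argmax returns the first maximum
    for qi, bi in enumerate(best):
        tied = np.flatnonzero(sim[qi] == sim[qi, bi])
        if len(tied) > 1 and len(set(labels[tied])) > 1:
            logger.debug("1-NN tie for query %d broken by input order", qi)
    return labels[best]


def confusion(y_true: Sequence, y_pred: Sequence,
              positive) -> ConfusionCounts:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    pos_t, pos_p = yt == positive, yp == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _safe_ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision, F1 and Matthews
    correlation from confusion counts; 0/0 ratios return 0 and are
    flagged in ``undefined_ratios``."""
    if c.total == 0:
        raise ValueError("cannot compute metrics of an empty confusion table")
    flags: list[str] = []
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = _safe_ratio(c.tp, c.tp + c.fn, flags, "sensitivity")
    specificity = _safe_ratio(c.tn, c.tn + c.fp, flags, "specificity")
    precision = _safe_ratio(c.tp, c.tp + c.fp, flags, "precision")
    f1 = _safe_ratio(2 * precision * sensitivity, precision + sensitivity,
                     flags, "f1")
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = _safe_ratio(c.tp * c.tn - c.fp * c.fn, denom, flags, "mcc")
    return MetricSet(accuracy=accuracy, sensitivity=sensitivity,
                     specificity=specificity, precision=precision, f1=f1,
                     mcc=mcc, undefined_ratios=tuple(flags))


def label_activity(ic50_umol: float) -> str:
    """Activity call from an IC50 in µmol: active iff strictly below 10."""
    if ic50_umol is None or (isinstance(ic50_umol, float)
                             and math.isnan(ic50_umol)):
        raise ValueError("missing IC50 value")
    if ic50_umol < 0:
        raise ValueError("negative IC50 value")
    return "active" if ic50_umol < ACTIVITY_THRESHOLD_UM else "inactive"


def _mean_metrics(metric_sets: Sequence[MetricSet]) -> MetricSet:
    keys = ["accuracy", "sensitivity", "specificity", "precision", "f1", "mcc"]
    means = {k: float(np.mean([getattr(m, k) for m in metric_sets]))
             for k in keys}
    return MetricSet(**means)


def infer_positive_label(labels: Sequence) -> str:
    """Positive class convention: 'active' if present, else the first
    label in sorted order."""
    unique = sorted(set(labels))
    return "active" if "active" in unique else unique[0]


def run_split_protocol(bits: np.ndarray, labels: Sequence,
                       protocol: SplitProtocol,
                       positive: Optional[str] = None) -> TaskResult:
    """Repeated stratified 80/20 evaluation of the 1-NN Tanimoto model.

    Per repeat: a seeded split, a tenfold CV on the training portion
    (pooled fold confusion counts), and prediction of the held-out 20%.
    Returns per-repeat metric sets plus their average; the external
    average is the headline number.
    """
    bits = np.atleast_2d(np.asarray(bits, dtype=np.uint8))
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two classes")
    if bits.shape[0] != labels.shape[0]:
        raise ValueError("fingerprint / label count mismatch")
    if bits.shape[0] < 10:
        raise ValueError("dataset too small for the 80/20 protocol")
    positive = positive or infer_positive_label(labels)
    external, cv = [], []
    indices = np.arange(bits.shape[0])
    for rep in range(protocol.repeats):
        rs = protocol.seed + rep
        strat = labels if protocol.stratify else None
        train_idx, test_idx = train_test_split(
            indices, train_size=protocol.train_fraction, random_state=rs,
            stratify=strat)
        xtr, ytr = bits[train_idx], labels[train_idx]
        xte, yte = bits[test_idx], labels[test_idx]
        if protocol.cv_folds and protocol.cv_folds >= 2:
            folds = StratifiedKFold(n_splits=protocol.cv_folds, shuffle=True,
                                    random_state=rs)
            pooled = ConfusionCounts(0, 0, 0, 0)
            for fit_i, val_i in folds.split(xtr, ytr):
                pred = one_nn_predict(xtr[fit_i], ytr[fit_i], xtr[val_i])
                pooled = pooled + confusion(ytr[val_i], pred, positive)
            cv.append(confusion_metrics(pooled))
        else:
            cv.append(None)
        pred = one_nn_predict(xtr, ytr, xte)
        external.append(confusion_metrics(confusion(yte, pred, positive)))
    return TaskResult(external=external, cv=cv)


def y_randomization(bits: np.ndarray, labels: Sequence,
                    protocol: SplitProtocol, rounds: int = 100,
                    seed: int = 0,
                    positive: Optional[str] = None) -> YRandResult:
    """Significance of the 1-NN model against label-shuffled refits.

    The original protocol result and ``rounds`` reruns on shuffled labels
    yield Z = (metric_ori - mean_rand) / sd_rand for MCC and accuracy; a
    zero shuffled spread flags the result as degenerate instead of
    dividing by zero.
    """
    if rounds < 2:
        raise ValueError("need at least two randomization rounds")
    labels = np.asarray(labels)
    positive = positive or infer_positive_label(labels)
    original = run_split_protocol(bits, labels, protocol, positive=positive)
    rng = np.random.default_rng(seed)
    rand_mcc, rand_acc = [], []
    for _ in range(rounds):
        shuffled = rng.permutation(labels)
        res = run_split_protocol(bits, shuffled, protocol, positive=positive)
        rand_mcc.append(res.external_mean.mcc)
        rand_acc.append(res.external_mean.accuracy)
    mcc_mean, mcc_sd = float(np.mean(rand_mcc)), float(np.std(rand_mcc, ddof=1))
    acc_mean, acc_sd = float(np.mean(rand_acc)), float(np.std(rand_acc, ddof=1))
    degenerate = mcc_sd == 0 or acc_sd == 0
    z_mcc = z_score(original.external_mean.mcc, mcc_mean, mcc_sd)
    z_acc = z_score(original.external_mean.accuracy, acc_mean, acc_sd)
    return YRandResult(
        mcc_ori=original.external_mean.mcc,
        acc_ori=original.external_mean.accuracy,
        mcc_rand_mean=mcc_mean, acc_rand_mean=acc_mean,
        mcc_rand_sd=mcc_sd, acc_rand_sd=acc_sd,
        z_mcc=z_mcc, z_acc=z_acc, rounds=rounds, degenerate=degenerate,
    )
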