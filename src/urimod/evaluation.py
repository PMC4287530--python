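"""Threshold-dependent metrics, ROC/AUC, and five-fold cross-validation.

Metrics follow the standard confusion-matrix definitions:

    Sn  = 100·TP/(TP+FN)        Sp  = 100·TN/(TN+FP)
    Acc = 100·(TP+TN)/N         MCC = (TP·TN − FP·FN)/√∏(marginals)

A window is called positive when its score ≥ threshold (ties positive).
Threshold sweeps run on the fixed grid −1.0 … 1.0 in steps of 0.1
(21 rows); AUC is always computed from the continuous scores (it equals
the Mann–Whitney statistic: the probability that a random positive
outscores a random negative, ties counted half).

Cross-validation deals positives and negatives separately into k folds
(window mode), or deals whole records so that no tRNA's windows are ever
split across folds (sequence mode). Out-of-fold scores are pooled into a
single report; per-fold AUCs are kept alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .encoders import encode_windows
from .svm import SVMParams, TrainedModel, decision_scores, train
from .windows import LabeledWindow, POSITIVE

THRESHOLD_GRID = tuple(round(-1.0 + 0.1 * i, 1) for i in range(21))


@dataclass(frozen=True)
class Confusion:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsRow:
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    mcc: float


@dataclass
class EvalReport:
    rows: list[MetricsRow]
    auc: float
    group: str = "all"
    n_pos: int = 0
    n_neg: int = 0
    best_mcc_threshold: float | None = None
    balanced_threshold: float | None = None  # min |Sn − Sp| row
    fold_aucs: list[float] = field(default_factory=list)
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None
    folds: np.ndarray | None = None

    def to_tsv(self, path: str | Path) -> None:
        lines = ["threshold\tsensitivity\tspecificity\taccuracy\tmcc"]
        for r in self.rows:
            lines.append(
                f"{r.threshold:.2f}\t{r.sensitivity:.2f}\t{r.specificity:.2f}"
                f"\t{r.accuracy:.2f}\t{r.mcc:.3f}"
            )
        lines.append(f"# AUC\t{self.auc:.3f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group": self.group,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "auc": self.auc,
            "best_mcc_threshold": self.best_mcc_threshold,
            "balanced_threshold": self.balanced_threshold,
            "fold_aucs": self.fold_aucs,
            "rows": [
                {
                    "threshold": r.threshold,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "accuracy": r.accuracy,
                    "mcc": r.mcc,
                }
                for r in self.rows
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def confusion_at(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> Confusion:
    """Confusion counts with the tie rule score ≥ threshold → positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError(
            f"{scores.shape[0]} scores but {labels.shape[0]} labels"
        )
    pred = scores >= threshold
    pos = labels == 1
    return Confusion(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(conf: Confusion, threshold: float = 0.0) -> MetricsRow:
    """Sn/Sp/Acc (percent) and MCC; any 0/0 ratio is reported as 0."""
    if conf.N == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = conf.TP, conf.FP, conf.TN, conf.FN
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / conf.N
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0
    return MetricsRow(threshold, sn, sp, acc, mcc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC from the continuous scores (Mann–Whitney; ties count half)."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def threshold_table(
    scores: Sequence[float],
    labels: Sequence[int],
    group: str = "all",
) -> EvalReport:
    """21-row sweep over the −1.0 … 1.0 grid plus continuous AUC.

    Flags the maximum-MCC row (ties resolved toward the threshold closest
    to 0.0) and the minimum-|Sn−Sp| row, the two conventions used to mark
    preferred operating points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rows = [metrics(confusion_at(scores, labels, t), t) for t in THRESHOLD_GRID]
    best_mcc = max(rows, key=lambda r: (r.mcc, -abs(r.threshold)))
    balanced = min(
        rows, key=lambda r: (abs(r.sensitivity - r.specificity), abs(r.threshold))
    )
    return EvalReport(
        rows=rows,
        auc=roc_auc(scores, labels),
        group=group,
        n_pos=int(np.sum(labels == 1)),
        n_neg=int(np.sum(labels == 0)),
        best_mcc_threshold=best_mcc.threshold,
        balanced_threshold=balanced.threshold,
        scores=scores,
        labels=labels,
    )


def _deal_round_robin(items: list, k: int, rng: np.random.Generator) -> dict:
    """Shuffle *items*, then deal them round-robin into k folds."""
    order = list(items)
    rng.shuffle(order)
    return {item: i % k for i, item in enumerate(order)}


def assign_folds(
    windows: Sequence[LabeledWindow],
    mode: str,
    k: int,
    seed: int,
) -> np.ndarray:
    """Fold index per window.

    ``window`` mode deals positives and negatives separately (stratified);
    ``sequence`` mode deals record ids, so all windows of one tRNA share a
    fold. Reproducible from *seed*.
    """
    rng = np.random.default_rng(seed)
    folds = np.empty(len(windows), dtype=int)
    if mode == "window":
        pos_idx = [i for i, w in enumerate(windows) if w.label == POSITIVE]
        neg_idx = [i for i, w in enumerate(windows) if w.label != POSITIVE]
        for idx in (pos_idx, neg_idx):
            fold_of = _deal_round_robin(idx, k, rng)
            for i in idx:
                folds[i] = fold_of[i]
    elif mode == "sequence":
        rec_ids = sorted({w.record_id for w in windows})
        fold_of = _deal_round_robin(rec_ids, k, rng)
        for i, w in enumerate(windows):
            folds[i] = fold_of[w.record_id]
    else:
        raise ValueError(f"mode must be 'window' or 'sequence', got {mode!r}")
    return folds


def cross_validate(
    windows: Sequence[LabeledWindow],
    scheme: str,
    params: SVMParams = SVMParams(),
    *,
    mode: str = "window",
    k: int = 5,
    seed: int = 0,
    dialect: str = "trnascan",
    group: str = "all",
) -> EvalReport:
    """k-fold cross-validation; pooled out-of-fold scores feed the report.

    Every window is scored exactly once, by the model trained on the other
    k−1 folds. Requires ≥k positives and ≥k negatives (window mode) or ≥k
    records (sequence mode) so that every training split sees both classes.
    """
    labels = np.array([1 if w.label == POSITIVE else 0 for w in windows])
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if mode == "window" and (n_pos < k or n_neg < k):
        raise ValueError(
            f"window-mode {k}-fold CV needs at least {k} windows per class; "
            f"got {n_pos} positive, {n_neg} negative"
        )
    if mode == "sequence" and len({w.record_id for w in windows}) < k:
        raise ValueError(f"sequence-mode {k}-fold CV needs at least {k} records")

    X = encode_windows(windows, scheme, dialect)
    folds = assign_folds(windows, mode, k, seed)
    scores = np.empty(len(windows))
    fold_aucs = []
    for fold in range(k):
        test = folds == fold
        model = train(X[~test], labels[~test], params, scheme=scheme)
        scores[test] = decision_scores(model, X[test])
        if len(set(labels[test].tolist())) == 2:
            fold_aucs.append(roc_auc(scores[test], labels[test]))

    report = threshold_table(scores, labels, group=group)
    report.fold_aucs = fold_aucs
    report.folds = folds
    return report


def kingdomwise_evaluate(
    model: TrainedModel,
    splits: Mapping[str, Sequence[LabeledWindow]],
    dialect: str = "trnascan",
) -> dict[str, EvalReport | None]:
    """Score each taxon group with a fixed model; pool everything as "all".

    Groups lacking either class map to ``None`` (not evaluable) instead of
    raising. Each group's windows enter the pooled "all" report exactly once.
    """
    out: dict[str, EvalReport | None] = {}
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for group, wins in splits.items():
        if not len(wins):
            out[group] = None
            continue
        X = encode_windows(wins, model.scheme, dialect)
        scores = decision_scores(model, X)
        labels = np.array([1 if w.label == POSITIVE else 0 for w in wins])
        all_scores.append(scores)
        all_labels.append(labels)
        if len(set(labels.tolist())) < 2:
            out[group] = None
        else:
            out[group] = threshold_table(scores, labels, group=group)
    if all_scores:
        pooled_s = np.concatenate(all_scores)
        pooled_l = np.concatenate(all_labels)
        if len(set(pooled_l.tolist())) == 2:
            out["all"] = threshold_table(pooled_s, pooled_l, group="all")
        else:
            out["all"] = None
    return out
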