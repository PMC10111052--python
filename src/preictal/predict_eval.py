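"""Classification, majority-vote smoothing and evaluation.

Epochs are classified preictal (positive, 1) vs interictal (0) by an
RBF-kernel SVM on standardized selected features. Raw per-epoch decisions
are then smoothed by a majority vote over non-overlapping 1-minute blocks
(12 five-second epochs): each block is relabeled to its modal raw label,
with a 6-6 tie going to preictal (a false alarm is preferred to a missed
seizure). Votes never cross a run boundary (a contiguous same-recording
span), and a trailing partial block is voted over its actual length.

Metrics, with preictal as the positive class:

    ACC = (TN + TP) / (TN + FP + TP + FN) * 100%
    F-score = 2 TP / (2 TP + FP + FN) * 100%
    FPR = FP / (FP + TN) * 100%

plus AUC from the pre-vote SVM decision values, and a false-prediction
rate per hour (preictal-voted blocks in interictal time / interictal hours
evaluated) -- a different quantity from the confusion-matrix FPR% and
reported separately.

Cross-validation is seizure-wise leave-one-out: each fold holds out the
whole preictal block of one seizure plus its matched interictal block, so
no epoch of a held-out seizure (or its autocorrelated neighbours) leaks
into training. Feature selection and standardization are fit on training
folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .feature_selection import (
    FeatureMatrix,
    SelectionResult,
    SelectionScheme,
    score_and_select,
)
from .io_eeg import EpochLabel

PREICTAL, INTERICTAL = int(EpochLabel.PREICTAL), int(EpochLabel.INTERICTAL)


@dataclass(frozen=True)
class ClassifierSpec:
    """RBF-SVM with library-default gamma and balanced class weights."""

    C: float = 1.0
    gamma: float | str = "scale"  # 1 / (n_features * feature variance)
    class_weight: str | None = "balanced"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    def build(self, seed: int = 0) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    SVC(
                        kernel="rbf",
                        C=self.C,
                        gamma=self.gamma,
                        class_weight=self.class_weight,
                        random_state=seed,
                    ),
                ),
            ]
        )


@dataclass
class PredictionSeries:
    """Per-epoch classifier output in temporal order.

    ``run_ids`` mark contiguous same-recording spans; voting blocks are
    assigned within runs and recorded in ``block_ids`` after smoothing.
    """

    raw: np.ndarray
    decision: np.ndarray
    run_ids: np.ndarray
    smoothed: np.ndarray | None = None
    block_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.int64)
        self.decision = np.asarray(self.decision, dtype=np.float64)
        self.run_ids = np.asarray(self.run_ids, dtype=np.int64)
        if not (len(self.raw) == len(self.decision) == len(self.run_ids)):
            raise ValueError("series arrays must align")

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def labels(self) -> np.ndarray:
        """Smoothed labels when voting has run, else the raw labels."""
        return self.raw if self.smoothed is None else self.smoothed


@dataclass
class FoldMetrics:
    acc: float
    auc: float
    fscore: float
    fpr: float
    fpr_per_hour: float
    n_test: int
    confusion: dict[str, int]


@dataclass
class EvalReport:
    """Per-fold metrics plus mean +/- sd aggregates (NaNs ignored)."""

    per_fold: list[FoldMetrics] = field(default_factory=list)

    def _vals(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.per_fold], dtype=float)

    def mean(self, name: str) -> float:
        v = self._vals(name)
        return float(np.nanmean(v)) if len(v) else float("nan")

    def sd(self, name: str) -> float:
        v = self._vals(name)
        return float(np.nanstd(v)) if len(v) else float("nan")

    def to_dict(self) -> dict:
        metrics = ("acc", "auc", "fscore", "fpr", "fpr_per_hour")
        return {
            "folds": [
                {m: getattr(f, m) for m in metrics}
                | {"n_test": f.n_test, "confusion": f.confusion}
                for f in self.per_fold
            ],
            "mean": {m: self.mean(m) for m in metrics},
            "sd": {m: self.sd(m) for m in metrics},
        }


def train(x: np.ndarray, y: np.ndarray, spec: ClassifierSpec = ClassifierSpec(),
          seed: int = 0) -> Pipeline:
    """Fit scaler + RBF-SVM; standardization learned on this data only."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training split must contain both classes")
    model = spec.build(seed)
    model.fit(np.asarray(x, dtype=np.float64), y)
    return model


def predict_series(model: Pipeline, x: np.ndarray,
                   run_ids: np.ndarray | None = None) -> PredictionSeries:
    x = np.asarray(x, dtype=np.float64)
    if run_ids is None:
        run_ids = np.zeros(len(x), dtype=np.int64)
    return PredictionSeries(
        raw=model.predict(x),
        decision=model.decision_function(x),
        run_ids=run_ids,
    )


def majority_vote(series: PredictionSeries,
                  window_epochs: int = 12) -> PredictionSeries:
    """Relabel each non-overlapping block to its modal raw label.

    Blocks are tiled within contiguous runs; a tie relabels to preictal
    and a trailing partial block is voted over its actual length. A
    unanimous block is never changed.
    """
    if window_epochs < 1:
        raise ValueError("window_epochs must be >= 1")
    n = len(series)
    smoothed = np.empty(n, dtype=np.int64)
    block_ids = np.empty(n, dtype=np.int64)
    block = 0
    start = 0
    for stop in range(1, n + 1):
        if stop == n or series.run_ids[stop] != series.run_ids[start]:
            for b0 in range(start, stop, window_epochs):
                b1 = min(b0 + window_epochs, stop)
                votes = series.raw[b0:b1]
                n_pre = int((votes == PREICTAL).sum())
                label = PREICTAL if n_pre >= (b1 - b0) - n_pre else INTERICTAL
                smoothed[b0:b1] = label
                block_ids[b0:b1] = block
                block += 1
            start = stop
    return PredictionSeries(
        raw=series.raw.copy(),
        decision=series.decision.copy(),
        run_ids=series.run_ids.copy(),
        smoothed=smoothed,
        block_ids=block_ids,
    )


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return {
        "tp": int(np.sum((y_true == PREICTAL) & (y_pred == PREICTAL))),
        "tn": int(np.sum((y_true == INTERICTAL) & (y_pred == INTERICTAL))),
        "fp": int(np.sum((y_true == INTERICTAL) & (y_pred == PREICTAL))),
        "fn": int(np.sum((y_true == PREICTAL) & (y_pred == INTERICTAL))),
    }


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int
                           ) -> dict[str, float]:
    """ACC / F-score / FPR in percent; undefined denominators give NaN."""
    total = tp + tn + fp + fn
    acc = 100.0 * (tn + tp) / total if total else float("nan")
    f_den = 2 * tp + fp + fn
    fscore = 100.0 * 2 * tp / f_den if f_den else float("nan")
    fpr = 100.0 * fp / (fp + tn) if (fp + tn) else float("nan")
    return {"acc": acc, "fscore": fscore, "fpr": fpr}


def evaluate(series: PredictionSeries, y_true: np.ndarray,
             interictal_hours: float | None = None) -> FoldMetrics:
    """Score one prediction stream against ground truth.

    ACC/F/FPR use the post-vote labels; AUC uses the pre-vote decision
    values. FPR per hour counts voted blocks that are preictal-labeled
    inside interictal truth, divided by the interictal hours evaluated
    (NaN when unavailable).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    if len(y_true) != len(series):
        raise ValueError("series and truth must align")
    cm = confusion_counts(y_true, series.labels)
    m = metrics_from_confusion(cm["tp"], cm["tn"], cm["fp"], cm["fn"])
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true == PREICTAL, series.decision))
    else:
        auc = float("nan")
    fpr_h = float("nan")
    if interictal_hours and series.block_ids is not None:
        fp_blocks = 0
        for b in np.unique(series.block_ids):
            sel = series.block_ids == b
            truth_inter = np.mean(y_true[sel] == INTERICTAL) > 0.5
            if truth_inter and series.labels[sel][0] == PREICTAL:
                fp_blocks += 1
        fpr_h = fp_blocks / interictal_hours
    return FoldMetrics(
        acc=m["acc"],
        auc=auc,
        fscore=m["fscore"],
        fpr=m["fpr"],
        fpr_per_hour=fpr_h,
        n_test=len(y_true),
        confusion=cm,
    )


def crossvalidate(
    fm: FeatureMatrix,
    groups: np.ndarray,
    scheme: SelectionScheme | str = SelectionScheme.SCORE,
    k: int | None = None,
    bins: int = 10,
    spec: ClassifierSpec = ClassifierSpec(),
    vote_window: int = 12,
    epoch_seconds: float = 5.0,
    seed: int = 0,
) -> tuple[EvalReport, list[SelectionResult]]:
    """Seizure-wise leave-one-out cross-validation.

    ``groups[i]`` assigns epoch i to a seizure (preictal block + matched
    interictal block share a group). Each fold holds one group out
    entirely; selection, standardization and the SVM are fit on the
    remaining folds and applied to the held-out one. Requires at least 3
    groups: with fewer preictal/interictal states per subject the fit
    overspecialises and fold estimates are meaningless.
    """
    if fm.labels is None:
        raise ValueError("feature matrix must carry labels")
    groups = np.asarray(groups, dtype=np.int64)
    if groups.shape != (fm.n_samples,):
        raise ValueError("groups must align with feature rows")
    fold_ids = np.unique(groups)
    if len(fold_ids) < 3:
        raise ValueError(
            f"seizure-wise CV needs >= 3 seizure groups, got {len(fold_ids)}; "
            "fewer preictal/interictal states lead to overfitting"
        )
    report = EvalReport()
    selections: list[SelectionResult] = []
    for g in fold_ids:
        test = groups == g
        train_idx = ~test
        sel = score_and_select(
            FeatureMatrix(
                fm.values[train_idx],
                list(fm.feature_names),
                fm.labels[train_idx],
            ),
            scheme=scheme,
            k=k,
            bins=bins,
        )
        cols = sel.selected
        model = train(
            fm.values[np.ix_(train_idx, cols)], fm.labels[train_idx],
            spec, seed,
        )
        # one run per contiguous same-label span in the held-out fold
        y_test = fm.labels[test]
        run_ids = np.zeros(int(test.sum()), dtype=np.int64)
        rid = 0
        for i in range(1, len(y_test)):
            if y_test[i] != y_test[i - 1]:
                rid += 1
            run_ids[i] = rid
        series = predict_series(model, fm.values[np.ix_(test, cols)], run_ids)
        series = majority_vote(series, vote_window)
        inter_h = float(np.sum(y_test == INTERICTAL)) * epoch_seconds / 3600.0
        report.per_fold.append(evaluate(series, y_test, inter_h or None))
        selections.append(sel)
    return report, selections
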