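"""Confusion-matrix metrics and leakage-safe cross-validated benchmarking.

Seizure detection is scored as binary classification with the seizure
class positive: accuracy = (TP+TN)/total, recall = TP/(TP+FN),
precision = TP/(TP+FP), F1 = harmonic mean of precision and recall.
A zero denominator yields 0 by convention (logged).

``cross_validate`` implements repeated stratified 80/20 splitting
(Monte-Carlo CV, the default) or classic stratified k-fold; the
resampler is fitted and applied ONLY to each training split — the test
split is never resampled, and the no-leakage invariant (no test row among
the synthesis parents) holds by construction and is asserted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import LabeledDataset
from .resampling import RESAMPLERS, ResampleConfig, ResampleResult
from .preprocessing import SegmentSet

__all__ = ["ConfusionMatrix", "EvalReport", "confusion", "metrics",
           "cross_validate", "benchmark"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with positive = seizure."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()))


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        warnings.warn("zero denominator in metric; returning 0 by "
                      "convention", stacklevel=3)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(accuracy, recall, precision, f1)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    rec = _safe_div(cm.tp, cm.tp + cm.fn)
    pre = _safe_div(cm.tp, cm.tp + cm.fp)
    f1 = _safe_div(2 * pre * rec, pre + rec)
    return acc, rec, pre, f1


@dataclass
class EvalReport:
    """Per-fold metrics plus their arithmetic means."""

    resampler: str
    classifier: str
    fold_metrics: list[dict] = field(default_factory=list)
    fold_seeds: list[int] = field(default_factory=list)

    def _mean(self, key: str) -> float:
        return float(np.mean([m[key] for m in self.fold_metrics]))

    @property
    def accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def recall(self) -> float:
        return self._mean("recall")

    @property
    def precision(self) -> float:
        return self._mean("precision")

    @property
    def f1(self) -> float:
        return self._mean("f1")

    def to_dict(self) -> dict:
        return {"resampler": self.resampler, "classifier": self.classifier,
                "folds": self.fold_metrics, "fold_seeds": self.fold_seeds,
                "mean": {"accuracy": self.accuracy, "recall": self.recall,
                         "precision": self.precision, "f1": self.f1}}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _as_dataset(data) -> LabeledDataset:
    if isinstance(data, LabeledDataset):
        return data
    if isinstance(data, SegmentSet):
        return LabeledDataset(data.flatten(), data.labels)
    raise TypeError("data must be a LabeledDataset or SegmentSet")


def _stratified_split(y: np.ndarray, test_frac: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """One stratified random train/test split (per-class proportional)."""
    test_idx = []
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        rows = rng.permutation(rows)
        n_test = max(1, round(test_frac * len(rows)))
        test_idx.append(rows[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    return train_idx, test_idx


def _fit_predict(classifier: str, train: LabeledDataset,
                 test_X: np.ndarray, seed: int) -> np.ndarray:
    if classifier == "1nn":
        from .model import knn_classifier
        return knn_classifier(train, test_X)
    raise KeyError(f"unknown classifier {classifier!r}")


def cross_validate(data, resampler: str = "none", classifier: str = "1nn",
                   n_folds: int = 5, test_frac: float = 0.2, seed: int = 0,
                   cfg: ResampleConfig | None = None,
                   cv: str = "monte-carlo") -> EvalReport:
    """Benchmark one resampler with repeated stratified splitting.

    Each fold: draw a stratified 80/20 train/test split (or take a
    classic stratified k-fold partition with ``cv='kfold'``), resample
    the training split only, fit the classifier on the resampled training
    data and score the untouched test split.

    The fold's resampler seed is derived from ``seed`` so the whole
    report is reproducible.  A test split without positives is flagged
    with a warning (recall falls to the 0 convention).
    """
    ds = _as_dataset(data)
    base_cfg = cfg or ResampleConfig()
    if resampler not in RESAMPLERS:
        raise KeyError(f"unknown resampler {resampler!r}")
    report = EvalReport(resampler=resampler, classifier=classifier)

    if cv == "kfold":
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed)
        splits = list(skf.split(ds.X, ds.y))
    elif cv == "monte-carlo":
        rng = np.random.default_rng(seed)
        splits = [_stratified_split(ds.y, test_frac, rng)
                  for _ in range(n_folds)]
    else:
        raise ValueError("cv must be 'monte-carlo' or 'kfold'")

    for fold, (train_idx, test_idx) in enumerate(splits):
        fold_seed = (seed * 1009 + fold) % (2 ** 31)
        train = ds.subset(train_idx)
        if len(np.unique(train.y)) < 2:
            raise ValueError(f"fold {fold}: training split lacks a class")
        if (ds.y[test_idx] == 1).sum() == 0:
            warnings.warn(f"fold {fold}: test split has no positive "
                          "samples; recall will be 0 by convention")
        fold_cfg = ResampleConfig(
            k_noise=base_cfg.k_noise, k_boundary=base_cfg.k_boundary,
            k_danger=base_cfg.k_danger, target_ratio=base_cfg.target_ratio,
            metric=base_cfg.metric, seed=fold_seed,
            keep_noise=base_cfg.keep_noise,
            partner_mode=base_cfg.partner_mode)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result: ResampleResult = RESAMPLERS[resampler](train, fold_cfg)
        # leakage guard: synthesis parents live in the train split only
        parent_orig = {int(train_idx[p.parent]) for p in result.provenance}
        assert parent_orig.isdisjoint(map(int, test_idx)), \
            "leakage: a test row appears among synthesis parents"
        y_pred = _fit_predict(classifier, result.dataset, ds.X[test_idx],
                              fold_seed)
        acc, rec, pre, f1 = metrics(confusion(ds.y[test_idx], y_pred))
        report.fold_metrics.append(
            {"accuracy": acc, "recall": rec, "precision": pre, "f1": f1,
             "n_synth": result.n_synth, "n_test": len(test_idx)})
        report.fold_seeds.append(fold_seed)
    return report


def benchmark(data, resamplers: tuple[str, ...] = ("none", "ros", "smote",
                                                   "blsmote", "svmsmote",
                                                   "bnnsmote"),
              **kwargs) -> dict[str, EvalReport]:
    """Run cross_validate for several resamplers on the same data."""
    return {name: cross_validate(data, resampler=name, **kwargs)
            for name in resamplers}


def benchmark_table(reports: dict[str, EvalReport]) -> str:
    """Plain-text comparison table (rows = resamplers)."""
    lines = [f"{'method':>10s} {'Rec (%)':>9s} {'Pre (%)':>9s} "
             f"{'F1 (%)':>9s} {'Acc (%)':>9s}"]
    for name, rep in reports.items():
        lines.append(f"{name:>10s} {100 * rep.recall:>9.2f} "
                     f"{100 * rep.precision:>9.2f} {100 * rep.f1:>9.2f} "
                     f"{100 * rep.accuracy:>9.2f}")
    return "\n".join(lines)
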