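"""ADHD-vs-TD classification from graph-measure features.

Feature vectors concatenate the 10 global AUC-over-sparsity measures with the
6 nodal AUC measures per ROI (706 features at 116 ROIs).  Features are ranked
and pruned by recursive feature elimination (RFE) and classified with a
linear-kernel SVM, random forest, or gradient boosting under stratified
k-fold cross-validation (9 folds by default).

Two modes are provided deliberately:

* ``nested``  -- RFE, imputation and standardization happen inside each
  training fold only; the held-out fold is untouched until prediction.
* ``circular`` -- RFE is run once on *all* subjects before cross-validation.
  This reproduces the circular-analysis error that inflates accuracy and is
  included only to audit that inflation.

Performance metrics use ADHD as the positive class and are computed from the
confusion counts pooled over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .metrics import GLOBAL_METRICS, MetricTable, NODAL_METRICS

__all__ = [
    "FeatureMatrix",
    "CVConfig",
    "ClassificationReport",
    "assemble_features",
    "rfe_select",
    "nested_cv_classify",
    "circular_cv_classify",
    "metrics_from_confusion",
]

MODELS = ("GB", "RF", "SVM")


@dataclass
class FeatureMatrix:
    """Subjects x named features, with binary labels (1 = ADHD)."""

    X: pd.DataFrame
    y: np.ndarray
    subject_ids: list

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class CVConfig:
    k: int = 9
    stratified: bool = True
    n_selected_features: int = 12
    rfe_step: float = 0.1          # fraction of remaining features per round
    seed: int = 0

    def validate(self, n_subjects: int) -> None:
        if not 2 <= self.k <= n_subjects:
            raise ValueError(f"k={self.k} invalid for n={n_subjects}")
        if self.n_selected_features < 1:
            raise ValueError("must keep at least one feature")


def assemble_features(tables: list[MetricTable], groups: list[str],
                      global_metrics=GLOBAL_METRICS,
                      nodal_metrics=NODAL_METRICS) -> FeatureMatrix:
    """Stack per-subject AUC summaries into a feature matrix.

    Column order is deterministic: global measures first, then one block per
    nodal metric with columns ``metric__ROI``.  Undefined values stay NaN here
    and are median-imputed inside training folds during cross-validation.
    Subjects whose features are all NaN are dropped with a warning.
    """
    if len(tables) != len(groups):
        raise ValueError("one group label per metric table required")
    rows, ids, y = [], [], []
    columns = None
    for t, g in zip(tables, groups):
        vals = [t.auc_global.get(m, np.nan) for m in global_metrics]
        names = list(global_metrics)
        for m in nodal_metrics:
            if m in t.auc_nodal.index:
                series = t.auc_nodal.loc[m]
                vals.extend(series.values)
                names.extend(f"{m}__{c}" for c in series.index)
        if columns is None:
            columns = names
        elif names != columns:
            raise ValueError(f"subject {t.subject_id}: feature set differs")
        if np.all(np.isnan(np.asarray(vals, dtype=float))):
            import warnings
            warnings.warn(f"subject {t.subject_id} has no defined features; "
                          "excluded", RuntimeWarning)
            continue
        rows.append(vals)
        ids.append(t.subject_id)
        y.append(1 if str(g) in ("ADHD", "1") else 0)
    X = pd.DataFrame(rows, index=ids, columns=columns)
    return FeatureMatrix(X, np.asarray(y), ids)


def _make_model(name: str, seed: int):
    if name == "SVM":
        return SVC(kernel="linear")
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "GB":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {MODELS}")


def _importance(model) -> np.ndarray:
    if hasattr(model, "coef_"):
        return np.abs(np.asarray(model.coef_)).ravel()
    return np.asarray(model.feature_importances_)


def rfe_select(X: np.ndarray, y: np.ndarray, model_name: str, n_keep: int,
               step: float = 0.1, seed: int = 0
               ) -> tuple[np.ndarray, list[int]]:
    """Recursive feature elimination on training data only.

    Repeatedly fits the model, ranks features by its importance (|w| for the
    linear SVM, impurity importance for the trees) and drops the lowest
    ``step`` fraction until ``n_keep`` remain.  Returns the kept column
    indices (in original order) and the full elimination order, first-removed
    first.
    """
    p = X.shape[1]
    if n_keep > p:
        raise ValueError(f"cannot keep {n_keep} of {p} features")
    current = np.arange(p)
    eliminated: list[int] = []
    while current.size > n_keep:
        model = _make_model(model_name, seed)
        model.fit(X[:, current], y)
        imp = _importance(model)
        n_drop = min(max(1, int(np.floor(step * current.size))),
                     current.size - n_keep)
        # stable worst-first ordering; ties resolved by column index
        order = np.lexsort((current, imp))
        drop = order[:n_drop]
        eliminated.extend(current[drop].tolist())
        current = np.delete(current, drop)
    return np.sort(current), eliminated


@dataclass
class ClassificationReport:
    classifier: str
    mode: str                           # "nested" or "circular"
    fold_confusions: list               # per fold (tp, fn, fp, tn)
    pooled: tuple                       # (TP, FN, FP, TN)
    metrics: dict = field(init=False)   # accuracy/sensitivity/... in percent
    selected_features: list = field(default_factory=list)  # per fold
    seed: int = 0

    def __post_init__(self) -> None:
        self.metrics = metrics_from_confusion(*self.pooled)

    def summary(self) -> str:
        tp, fn, fp, tn = self.pooled
        lines = [f"{self.classifier} ({self.mode} CV, seed={self.seed})",
                 f"  pooled confusion: TP={tp} FN={fn} FP={fp} TN={tn}"]
        for k, v in self.metrics.items():
            lines.append(f"  {k:>12}: " + ("missing" if np.isnan(v)
                                           else f"{v:.1f}%"))
        return "\n".join(lines)


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV in percent (one decimal).

    A metric whose denominator is zero is reported as NaN (missing).
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be non-negative")

    def pct(num, den):
        return round(100.0 * num / den, 1) if den > 0 else float("nan")

    n = tp + fn + fp + tn
    return {
        "accuracy": pct(tp + tn, n),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }


def _folds(y: np.ndarray, config: CVConfig):
    cls = StratifiedKFold if config.stratified else KFold
    kf = cls(n_splits=config.k, shuffle=True, random_state=config.seed)
    return list(kf.split(np.zeros_like(y), y))


def _prepare(train: np.ndarray, test: np.ndarray, scale: bool
             ) -> tuple[np.ndarray, np.ndarray]:
    """Median-impute (train statistics only) and optionally standardize."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    tr = np.where(np.isnan(train), med, train)
    te = np.where(np.isnan(test), med, test)
    if scale:
        mu = tr.mean(axis=0)
        sd = tr.std(axis=0)
        sd[sd == 0] = 1.0
        tr = (tr - mu) / sd
        te = (te - mu) / sd
    return tr, te


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    return tp, fn, fp, tn


def nested_cv_classify(features: FeatureMatrix, config: CVConfig | None = None,
                       model_name: str = "GB") -> ClassificationReport:
    """Stratified k-fold CV with RFE redone inside every training fold."""
    config = config or CVConfig()
    config.validate(len(features.y))
    X = features.X.values.astype(float)
    y = features.y
    scale = model_name == "SVM"
    fold_conf, selected = [], []
    for train_idx, test_idx in _folds(y, config):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 1:
            raise ValueError("a fold lost one of the classes; use stratified CV")
        tr, te = _prepare(X[train_idx], X[test_idx], scale)
        keep, _ = rfe_select(tr, y[train_idx], model_name,
                             config.n_selected_features, config.rfe_step,
                             config.seed)
        model = _make_model(model_name, config.seed)
        model.fit(tr[:, keep], y[train_idx])
        pred = model.predict(te[:, keep])
        fold_conf.append(_confusion(y[test_idx], pred))
        selected.append([features.X.columns[i] for i in keep])
    pooled = tuple(int(x) for x in np.array(fold_conf).sum(axis=0))
    return ClassificationReport(model_name, "nested", fold_conf, pooled,
                                selected_features=selected, seed=config.seed)


def circular_cv_classify(features: FeatureMatrix,
                         config: CVConfig | None = None,
                         model_name: str = "GB") -> ClassificationReport:
    """Same CV, but RFE runs once on all subjects first (circular analysis)."""
    config = config or CVConfig()
    config.validate(len(features.y))
    X = features.X.values.astype(float)
    y = features.y
    scale = model_name == "SVM"
    X_all, _ = _prepare(X, X, scale)
    keep, _ = rfe_select(X_all, y, model_name, config.n_selected_features,
                         config.rfe_step, config.seed)
    fold_conf = []
    for train_idx, test_idx in _folds(y, config):
        tr, te = _prepare(X[train_idx], X[test_idx], scale)
        model = _make_model(model_name, config.seed)
        model.fit(tr[:, keep], y[train_idx])
        pred = model.predict(te[:, keep])
        fold_conf.append(_confusion(y[test_idx], pred))
    pooled = tuple(int(x) for x in np.array(fold_conf).sum(axis=0))
    names = [features.X.columns[i] for i in keep]
    return ClassificationReport(model_name, "circular", fold_conf, pooled,
                                selected_features=[names] * config.k,
                                seed=config.seed)
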