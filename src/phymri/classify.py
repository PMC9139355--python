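"""Multiclass classifier grid, cross-validation protocol and metrics.

Nine classifier families (naïve Bayes, logistic regression, polynomial-
kernel SVM, 3-nearest-neighbors, decision tree, one-hidden-layer MLP with
#features + #classes neurons, AdaBoost over decision trees, random forest,
bagged randomized trees) are evaluated over every data-set × VOI
combination with stratified tenfold cross-validation.  Per-class
one-vs-rest metrics (sensitivity, specificity, precision, F1, binary
accuracy, AUROC) are averaged over folds and then weighted by class
support.  Standard learners are delegated to scikit-learn; the bespoke
content here is the protocol, the metrics, and the 9 × 5 × 3 model grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

from .constants import DATASET_IMAGES, ENTITY_LABELS, VOI_CHOICES

__all__ = [
    "CLASSIFIER_FAMILIES", "ClassifierSpec", "build_classifier",
    "EvaluationReport", "weighted_metrics", "cross_validate",
    "evaluate_test", "run_model_grid", "default_grid_specs",
]

CLASSIFIER_FAMILIES = ("NB", "Log", "SVM", "kNN", "DT", "MLP", "AdaBoost",
                       "RF", "Bagging")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its fixed hyperparameters.

    Stated defaults: kNN k = 3; SVM polynomial kernel (degree 1, C = 1);
    MLP one hidden layer with #features + #classes neurons; AdaBoost over
    pruned decision trees (10 rounds); bagging over randomized trees
    (10 bags); random forest with 100 trees.
    """

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")


def build_classifier(spec: ClassifierSpec, n_features: int | None = None,
                     n_classes: int = 5):
    """Instantiate a trainable model for a spec.

    ``n_features`` sizes the MLP hidden layer (#features + #classes).
    Scale-sensitive learners (Log, SVM, kNN, MLP) are wrapped in a
    standardizing pipeline.
    """
    p = dict(spec.params)
    seed = spec.seed
    fam = spec.family
    if fam == "NB":
        return GaussianNB(**p)
    if fam == "Log":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=1000, **p))
    if fam == "SVM":
        p.setdefault("degree", 1)
        p.setdefault("C", 1.0)
        return make_pipeline(StandardScaler(),
                             SVC(kernel="poly", probability=True,
                                 random_state=seed, **p))
    if fam == "kNN":
        p.setdefault("n_neighbors", 3)
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**p))
    if fam == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if fam == "MLP":
        hidden = (n_features or 10) + n_classes
        p.setdefault("hidden_layer_sizes", (hidden,))
        p.setdefault("max_iter", 500)
        return make_pipeline(StandardScaler(),
                             MLPClassifier(random_state=seed, **p))
    if fam == "AdaBoost":
        p.setdefault("n_estimators", 10)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3, random_state=seed),
            random_state=seed, **p)
    if fam == "RF":
        p.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **p)
    if fam == "Bagging":
        p.setdefault("n_estimators", 10)
        return BaggingClassifier(estimator=ExtraTreeClassifier(random_state=seed),
                                 random_state=seed, **p)
    raise ValueError(fam)  # unreachable, guarded by the spec


@dataclass
class EvaluationReport:
    """Per-class and weighted metrics for one classifier evaluation."""

    classifier: str
    per_class: pd.DataFrame  # rows = classes, metric columns
    weighted: dict  # metric -> support-weighted average
    confusion: pd.DataFrame  # pooled confusion matrix, rows = truth
    error_count: int
    overall_accuracy: float  # plain fraction correct
    n_cases: int
    seed: int = 0
    dataset: str | None = None
    voi: str | None = None


def _per_class_from_confusion(cm: np.ndarray) -> pd.DataFrame:
    """One-vs-rest sensitivity/specificity/precision/F1/accuracy per class."""
    n = cm.sum()
    rows = []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * prec * sens / (prec + sens)
              if prec + sens and np.isfinite(prec + sens) else 0.0)
        acc = (tp + tn) / n if n else np.nan
        rows.append({"sensitivity": sens, "specificity": spec,
                     "precision": prec, "f_score": f1, "accuracy": acc,
                     "support": int(tp + fn)})
    return pd.DataFrame(rows)


def weighted_metrics(confusion: pd.DataFrame | np.ndarray,
                     scores: np.ndarray | None = None,
                     y_true: np.ndarray | None = None,
                     classes: list | None = None) -> tuple[pd.DataFrame, dict]:
    """Per-class one-vs-rest metrics and their support-weighted averages.

    ``scores`` (cases × classes membership scores) with ``y_true`` adds a
    trapezoidal one-vs-rest AUROC per class.  Classes with zero support
    are excluded from the weighting.
    """
    cm = np.asarray(confusion, dtype=float)
    if classes is None:
        classes = (list(confusion.index)
                   if isinstance(confusion, pd.DataFrame)
                   else list(range(cm.shape[0])))
    per = _per_class_from_confusion(cm)
    per.index = classes
    if scores is not None and y_true is not None:
        aurocs = []
        for ci, cls in enumerate(classes):
            ind = (np.asarray(y_true) == cls).astype(int)
            if ind.sum() in (0, len(ind)):
                aurocs.append(np.nan)
            else:
                aurocs.append(roc_auc_score(ind, scores[:, ci]))
        per["auroc"] = aurocs
    support = per["support"].to_numpy(dtype=float)
    weighted = {}
    for metric in [c for c in per.columns if c != "support"]:
        vals = per[metric].to_numpy(dtype=float)
        ok = (support > 0) & np.isfinite(vals)
        weighted[metric] = (float(np.average(vals[ok], weights=support[ok]))
                            if ok.any() else float("nan"))
    return per, weighted


def _score_matrix(model, X, classes):
    """Per-class membership scores aligned to ``classes``."""
    proba = model.predict_proba(X)
    model_classes = list(model.classes_)
    out = np.zeros((len(X), len(classes)))
    for ci, cls in enumerate(classes):
        if cls in model_classes:
            out[:, ci] = proba[:, model_classes.index(cls)]
    return out


def cross_validate(spec: ClassifierSpec, table: pd.DataFrame,
                   labels: pd.Series, folds: int = 10, seed: int = 0,
                   smote: str = "fold", smote_k: int = 5) -> EvaluationReport:
    """Stratified k-fold cross-validation of one classifier.

    ``smote`` controls class balancing: ``"fold"`` (default) applies SMOTE
    to each training fold only; ``"pre"`` balances the full table before
    splitting (the historical protocol — optimistic because synthetic
    neighbors of validation cases leak into training); ``None`` disables
    balancing.  Per-class metrics are averaged over folds, then weighted
    by class support.  Falls back to unstratified folds with a warning if
    the smallest class has fewer members than ``folds``.
    """
    from .selection import smote_balance

    X_df, y_sr = table, pd.Series(np.asarray(labels))
    if smote == "pre":
        X_df, y_sr = smote_balance(X_df, y_sr, seed=seed, k=smote_k)
    X = X_df.to_numpy(dtype=float)
    y = np.asarray(y_sr)
    classes = [c for c in ENTITY_LABELS if c in set(y)] or \
        sorted(set(y), key=str)
    n_classes = len(classes)

    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
        splits = splitter.split(X, y)
    else:
        warnings.warn("smallest class has fewer members than folds; "
                      "falling back to unstratified folds")
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)

    cm_total = np.zeros((n_classes, n_classes))
    fold_frames = []
    for fold_i, (tr, va) in enumerate(splits):
        Xtr, ytr = X[tr], y[tr]
        if smote == "fold":
            df_tr = pd.DataFrame(Xtr, columns=table.columns)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df_tr, ytr_sr = smote_balance(df_tr, pd.Series(ytr),
                                              seed=seed + fold_i, k=smote_k)
            Xtr, ytr = df_tr.to_numpy(dtype=float), np.asarray(ytr_sr)
        model = build_classifier(spec, n_features=X.shape[1],
                                 n_classes=n_classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        pred = model.predict(X[va])
        scores = _score_matrix(model, X[va], classes)
        cm = np.zeros((n_classes, n_classes))
        for t, pcls in zip(y[va], pred):
            cm[classes.index(t), classes.index(pcls)] += 1
        cm_total += cm
        per, _ = weighted_metrics(cm, scores, y[va], classes)
        fold_frames.append(per)

    # average per-class metrics over folds (NaN-aware), weight by support
    stacked = pd.concat(fold_frames)
    per_class = stacked.groupby(stacked.index, sort=False).mean()
    per_class = per_class.loc[classes]
    per_class["support"] = [int((y == c).sum()) for c in classes]
    support = per_class["support"].to_numpy(dtype=float)
    weighted = {}
    for metric in [c for c in per_class.columns if c != "support"]:
        vals = per_class[metric].to_numpy(dtype=float)
        ok = (support > 0) & np.isfinite(vals)
        weighted[metric] = (float(np.average(vals[ok], weights=support[ok]))
                            if ok.any() else float("nan"))
    confusion = pd.DataFrame(cm_total.astype(int), index=classes,
                             columns=classes)
    errors = int(cm_total.sum() - np.trace(cm_total))
    return EvaluationReport(
        classifier=spec.family, per_class=per_class, weighted=weighted,
        confusion=confusion, error_count=errors,
        overall_accuracy=float(np.trace(cm_total) / cm_total.sum()),
        n_cases=len(y), seed=seed,
    )


def evaluate_test(model, test_table: pd.DataFrame, test_labels,
                  feature_list: list | None = None) -> EvaluationReport:
    """Single-pass evaluation of a fitted model on an independent cohort.

    ``feature_list`` (the model's selected features) is checked against
    the table columns; classes absent from the test set receive zero
    weight in the weighted averages.
    """
    if feature_list is not None:
        missing = [f for f in feature_list if f not in test_table.columns]
        if missing:
            raise ValueError(f"test table is missing columns {missing}")
        test_table = test_table[feature_list]
    X = test_table.to_numpy(dtype=float)
    y = np.asarray(test_labels)
    classes = [c for c in ENTITY_LABELS if c in set(list(model.classes_) + list(y))]
    pred = model.predict(X)
    scores = _score_matrix(model, X, classes)
    cm = np.zeros((len(classes), len(classes)))
    for t, pcls in zip(y, pred):
        cm[classes.index(t), classes.index(pcls)] += 1
    per, weighted = weighted_metrics(cm, scores, y, classes)
    confusion = pd.DataFrame(cm.astype(int), index=classes, columns=classes)
    errors = int(cm.sum() - np.trace(cm))
    return EvaluationReport(
        classifier=type(model).__name__, per_class=per, weighted=weighted,
        confusion=confusion, error_count=errors,
        overall_accuracy=float(np.trace(cm) / cm.sum()), n_cases=len(y),
    )


def default_grid_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(f, seed=seed) for f in CLASSIFIER_FAMILIES]


def run_model_grid(cohort_tables: dict, specs: list[ClassifierSpec] | None = None,
                   folds: int = 10, seed: int = 0,
                   smote: str = "fold") -> dict:
    """Cross-validate every classifier on every (data set, VOI) table.

    ``cohort_tables`` maps ``(data_set, voi)`` → ``(table, labels)`` for
    the 5 data-set combinations × 3 VOI choices; with the default nine
    specs this yields the full 135-model grid.  Returns reports keyed
    ``(family, data_set, voi)``.
    """
    if specs is None:
        specs = default_grid_specs(seed)
    if not cohort_tables:
        raise ValueError("no cohort tables provided")
    missing = [key for key, val in cohort_tables.items() if val is None]
    if missing:
        raise ValueError(f"missing cohort tables for {missing}")
    reports = {}
    for (ds, voi), (table, labels) in cohort_tables.items():
        for spec in specs:
            rep = cross_validate(spec, table, labels, folds=folds, seed=seed,
                                 smote=smote)
            rep.dataset, rep.voi = ds, voi
            reports[(spec.family, ds, voi)] = rep
    return reports


def grid_heatmap(reports: dict, metric: str = "auroc") -> pd.DataFrame:
    """Classifier × (data set, VOI) matrix of one weighted metric."""
    rows = {}
    for (fam, ds, voi), rep in reports.items():
        rows.setdefault(fam, {})[(ds, voi)] = rep.weighted.get(metric, np.nan)
    return pd.DataFrame(rows).T.sort_index()
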