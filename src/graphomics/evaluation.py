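"""Cross-validated comparison of GNN patient embeddings against raw layers.

The protocol mirrors the standard single-omics baseline study: a
gradient-boosted tree classifier (XGBoost) is fitted either on one layer's
raw feature matrix or on the GNN patient embeddings, under stratified
k-fold cross-validation, and a five-metric panel (accuracy, precision,
recall, F1, AUC) is averaged over folds.

By default the GNN is retrained inside every fold with the test patients'
labels withheld (their expression edges remain in the graph — standard
transductive semi-supervised learning, but no label leakage).  Setting
``transductive=True`` reproduces the train-on-everything variant where one
model trained on all labels supplies embeddings for every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, precision_recall_fscore_support,
                             roc_auc_score)
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import InputError
from .model import MultiOmicsGNN, TrainConfig, cohort_graph

METRIC_ROWS = ("accuracy", "precision", "recall", "f1", "auc")

RAW_METHODS = ("raw_mrna", "raw_mirna", "raw_circrna", "raw_methylation")
ALL_METHODS = ("gnn_embeddings",) + RAW_METHODS


@dataclass
class MetricPanel:
    """Fold-averaged classification metrics, with per-fold values retained."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    per_fold: pd.DataFrame = field(repr=False, default=None)

    def to_series(self, name: str = "value") -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in METRIC_ROWS}, name=name)

    @classmethod
    def from_folds(cls, folds: list[dict[str, float]]) -> "MetricPanel":
        frame = pd.DataFrame(folds)
        means = frame.mean()
        return cls(**{m: float(means[m]) for m in METRIC_ROWS}, per_fold=frame)


def kfold_split(labels: pd.Series | np.ndarray, k: int, seed: int = 0,
                stratified: bool = True) -> np.ndarray:
    """Partition samples into k folds; returns a fold id per sample.

    Stratification preserves class proportions and requires every class to
    have at least k members.
    """
    y = np.asarray(labels)
    if k < 2:
        raise InputError("k must be >= 2")
    if stratified:
        classes, counts = np.unique(y, return_counts=True)
        small = classes[counts < k]
        if len(small):
            raise InputError(
                f"class {small[0]!r} has fewer than k={k} members; "
                "stratified folding is impossible")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds[test_idx] = i
    return folds


def fit_baseline(features: np.ndarray, labels: np.ndarray,
                 train_idx: np.ndarray, seed: int = 0, n_estimators: int = 100):
    """Gradient-boosted tree classifier fitted on the training rows only."""
    from xgboost import XGBClassifier

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise InputError("features and labels are not row-aligned")
    train_idx = np.asarray(train_idx, dtype=int)
    y_train = y[train_idx]
    if len(np.unique(y_train)) < 2:
        raise InputError("training set contains a single class")
    clf = XGBClassifier(
        n_estimators=n_estimators, max_depth=3, learning_rate=0.3,
        tree_method="hist", n_jobs=1, random_state=seed)
    # xgboost wants integer class codes covering 0..C-1 on the training rows
    classes = np.unique(y)
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[c] for c in y_train])
    if len(np.unique(y_codes)) != len(classes):
        # a class absent from training: refuse rather than silently re-code
        missing = [c for c in classes if c not in set(y_train)]
        raise InputError(f"class {missing[0]!r} absent from the training rows")
    clf.fit(X[train_idx], y_codes)
    clf._graphomics_classes = classes
    return clf


def compute_metrics(y_true, y_prob, classes) -> dict[str, float]:
    """One fold's metric dict: accuracy from argmax, weighted precision /
    recall / F1, and one-vs-rest macro AUC for more than two classes."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    classes = list(classes)
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise InputError("probability rows must sum to 1")
    unknown = set(y_true) - set(classes)
    if unknown:
        raise InputError(f"class {sorted(unknown)[0]!r} missing from probability columns")
    pred = np.array([classes[i] for i in y_prob.argmax(axis=1)])
    acc = accuracy_score(y_true, pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, pred, labels=classes, average="weighted", zero_division=0)
    present = [c for c in classes if c in set(y_true)]
    if len(present) < 2:
        auc = np.nan
    elif len(classes) == 2:
        auc = roc_auc_score((y_true == classes[1]).astype(int), y_prob[:, 1])
    else:
        cols = [classes.index(c) for c in present]
        sub = y_prob[:, cols]
        sub = sub / sub.sum(axis=1, keepdims=True)
        auc = roc_auc_score(y_true, sub, multi_class="ovr", average="macro",
                            labels=present)
    return {"accuracy": float(acc), "precision": float(prec),
            "recall": float(rec), "f1": float(f1), "auc": float(auc)}


@dataclass
class ComparisonResult:
    panels: dict[str, MetricPanel]

    def to_frame(self) -> pd.DataFrame:
        """Metric rows x method columns, the familiar comparison-table shape."""
        return pd.DataFrame({m: p.to_series() for m, p in self.panels.items()})


def compare_methods(cohort, methods=ALL_METHODS, k: int = 5, seed: int = 0,
                    train_config: TrainConfig | None = None,
                    transductive: bool = False,
                    top_q_features: int | None = None) -> ComparisonResult:
    """Cross-validated metric panels for GNN embeddings vs raw single layers.

    Per fold the GNN is (re)trained on the training patients, all patients
    are embedded, an XGBoost classifier is fitted on the training
    embeddings and evaluated on the held-out patients; raw methods fit
    XGBoost directly on a layer's sample x feature matrix.
    ``top_q_features`` optionally restricts raw layers to the q
    highest-variance features (computed on training rows only).
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise InputError(f"unknown method {sorted(unknown)[0]!r}; "
                         f"choose from {ALL_METHODS}")
    labels = cohort.labels
    y = labels.to_numpy()
    classes = sorted(np.unique(y))
    folds = kfold_split(y, k=k, seed=seed, stratified=True)

    graph = None
    shared_results = None
    if "gnn_embeddings" in methods:
        graph = cohort_graph(cohort)
        cfg = train_config or TrainConfig(seed=seed)
        if transductive:
            shared_results = MultiOmicsGNN(graph, labels=labels, config=cfg).fit()

    feature_sets: dict[str, np.ndarray] = {}
    for method in methods:
        if method.startswith("raw_"):
            layer = method[len("raw_"):]
            if layer not in cohort.matrices:
                raise InputError(f"cohort has no layer for method {method!r}")
            feature_sets[method] = cohort.matrices[layer].values.T  # samples x features

    fold_metrics: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    for fold in range(k):
        test_mask = folds == fold
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        for method in methods:
            if method == "gnn_embeddings":
                if transductive:
                    emb = shared_results.patient_embeddings().to_numpy()
                else:
                    cfg = train_config or TrainConfig(seed=seed)
                    res = MultiOmicsGNN(graph, labels=labels, config=cfg).fit(
                        train_mask=~test_mask)
                    emb = res.patient_embeddings().to_numpy()
                X = emb
            else:
                X = feature_sets[method]
                if top_q_features is not None and top_q_features < X.shape[1]:
                    var = X[train_idx].var(axis=0)
                    keep = np.argsort(-var, kind="stable")[:top_q_features]
                    X = X[:, np.sort(keep)]
            clf = fit_baseline(X, y, train_idx, seed=seed)
            prob = clf.predict_proba(X[test_idx])
            fold_metrics[method].append(compute_metrics(y[test_idx], prob, classes))
    panels = {m: MetricPanel.from_folds(fold_metrics[m]) for m in methods}
    return ComparisonResult(panels=panels)


def gnn_heldout_accuracy(cohort, train_config: TrainConfig | None = None,
                         test_fraction: float = 0.3, seed: int = 0,
                         ) -> tuple[float, float]:
    """Accuracy of the GNN's own softmax classifier on a stratified held-out
    patient set, together with the majority-class rate on that set."""
    if not 0 < test_fraction < 1:
        raise InputError("test_fraction must lie in (0, 1)")
    labels = cohort.labels
    y = labels.to_numpy()
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_mask[rng.choice(idx, size=n_test, replace=False)] = True
    graph = cohort_graph(cohort)
    cfg = train_config or TrainConfig(seed=seed)
    res = MultiOmicsGNN(graph, labels=labels, config=cfg).fit(train_mask=~test_mask)
    acc = res.accuracy(mask=test_mask)
    _, counts = np.unique(y[test_mask], return_counts=True)
    majority = counts.max() / counts.sum()
    return acc, float(majority)
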