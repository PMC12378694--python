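"""Outcome classification: stratified 3:1 split, linear SVM, C grid search.

The positive class is nSF (seizure recurrence).  Standardization has two
modes: "train-only" (scaler fitted on the training partition; the default) and
"study-literal" (z-scores over the full table before splitting, reproducing
the study's published order of operations, which leaks test statistics into
the scaler and is kept only for faithful reproduction).  Model selection is a
grid search over C with 5-fold stratified CV inside the training set; ties in
CV accuracy go to the smallest C (strongest regularization).  Headline
metrics are the CV fold means (accuracy, sensitivity, specificity, F1) plus
held-out-test ROC/AUC from the decision scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .config import ModelConfig
from .errors import InvalidInputError, StratificationError
from .schema import OUTCOME_COLUMN, PREDICTOR_COLUMNS
from .seeds import stage_rng


@dataclass
class Scaler:
    mean: pd.Series
    sd: pd.Series
    constant_columns: list

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        cols = [c for c in df.columns if c not in self.constant_columns]
        out[cols] = (df[cols] - self.mean[cols]) / self.sd[cols]
        return out


@dataclass
class ModelReport:
    best_c: float
    train_index: np.ndarray
    test_index: np.ndarray
    cv_metrics: dict
    cv_confusion: np.ndarray
    test_metrics: dict
    roc_points: np.ndarray  # (n, 2) fpr/tpr
    auc: float
    weights: np.ndarray
    bias: float
    feature_names: list
    grid_results: pd.DataFrame = field(default_factory=pd.DataFrame)
    X_train: Optional[pd.DataFrame] = None
    y_train: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return dict(
            best_c=self.best_c,
            train_index=self.train_index.tolist(),
            test_index=self.test_index.tolist(),
            cv_metrics=self.cv_metrics,
            cv_confusion=self.cv_confusion.tolist(),
            test_metrics=self.test_metrics,
            roc_points=self.roc_points.tolist(),
            auc=self.auc,
            weights=self.weights.tolist(),
            bias=self.bias,
            feature_names=list(self.feature_names),
        )


def _class_counts(y: np.ndarray) -> dict:
    vals, counts = np.unique(y, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def split_cohort(y, config: ModelConfig, seed: int | None = None):
    """Stratified train/test indices at the configured ratio.

    Total training size is round(ratio * n); per-class sizes follow
    largest-remainder rounding (ties broken toward the larger class, then by
    label order), so a 30/26 cohort splits 42:14 as 23+19 / 7+7.
    """
    y = np.asarray(y)
    counts = _class_counts(y)
    if len(counts) < 2:
        raise StratificationError("both classes must be present")
    if min(counts.values()) < 4:
        raise StratificationError("each class needs >= 4 members to stratify")
    n = len(y)
    n_train = int(round(config.split_ratio * n))
    quotas = {k: config.split_ratio * v for k, v in counts.items()}
    base = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = n_train - sum(base.values())
    order = sorted(
        counts, key=lambda k: (-(quotas[k] - base[k]), -counts[k], str(k))
    )
    for k in order[:leftover]:
        base[k] += 1
    rng = stage_rng(config.seed if seed is None else seed, "split")
    train_idx, test_idx = [], []
    for k in sorted(counts, key=str):
        idx = np.flatnonzero(y == k)
        perm = rng.permutation(idx)
        train_idx.extend(perm[: base[k]])
        test_idx.extend(perm[base[k] :])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def standardize(train: pd.DataFrame, test: pd.DataFrame, mode: str = "train-only"):
    """Z-score feature columns; returns (train_scaled, test_scaled, scaler).

    "train-only": statistics from the training partition only.
    "study-literal": statistics from the pooled table (the study's order —
    scale first, split later), reproduced deliberately, leakage documented.
    Constant columns are flagged and passed through unscaled.
    """
    import warnings

    if mode == "study-literal":
        ref = pd.concat([train, test], axis=0)
    elif mode == "train-only":
        ref = train
    else:
        raise InvalidInputError(f"unknown standardization mode {mode!r}")
    mean = ref.mean()
    sd = ref.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant columns passed through unscaled: {constant}", stacklevel=2)
    scaler = Scaler(mean=mean, sd=sd, constant_columns=constant)
    return scaler.transform(train), scaler.transform(test), scaler


def stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Index folds with both classes in each fold."""
    folds = [[] for _ in range(n_folds)]
    for k in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == k))
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    folds = [np.sort(np.asarray(f)) for f in folds]
    for f in folds:
        if len(np.unique(y[f])) < 2:
            raise StratificationError("a CV fold lacks one of the classes")
    return folds


def fit_linear_svm(X: np.ndarray, y01: np.ndarray, c: float):
    """Soft-margin hinge-loss linear SVM; labels {0: SF, 1: nSF}.

    Returns (weights, bias, decision function).
    """
    if len(np.unique(y01)) < 2:
        raise InvalidInputError("single-class input")
    clf = SVC(kernel="linear", C=c, tol=1e-8)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y01, dtype=int))
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    return w, b, (lambda Z: np.asarray(Z, dtype=float) @ w + b)


def evaluate(scores: np.ndarray, y01: np.ndarray) -> dict:
    """Threshold-0 metrics plus ROC/AUC from continuous decision scores."""
    import warnings

    scores = np.asarray(scores, dtype=float)
    y01 = np.asarray(y01, dtype=int)
    pred = (scores > 0).astype(int)
    tp = int(np.sum((pred == 1) & (y01 == 1)))
    tn = int(np.sum((pred == 0) & (y01 == 0)))
    fp = int(np.sum((pred == 1) & (y01 == 0)))
    fn = int(np.sum((pred == 0) & (y01 == 1)))
    n = len(y01)
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    # zero-division convention: no positive predictions -> precision/F1 = 0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
    out = dict(
        accuracy=acc, sensitivity=sens, specificity=spec, precision=prec, f1=f1,
        confusion=np.array([[tn, fp], [fn, tp]]),
    )
    if len(np.unique(y01)) == 2:
        fpr, tpr, _ = roc_curve(y01, scores)
        out["roc"] = np.column_stack([fpr, tpr])
        out["auc"] = float(sk_auc(fpr, tpr))
    else:
        warnings.warn("one-class data: ROC/AUC undefined", stacklevel=2)
        out["roc"], out["auc"] = None, np.nan
    return out


def grid_search_c(X: pd.DataFrame, y01: np.ndarray, config: ModelConfig,
                  seed: int | None = None):
    """Per-C mean CV accuracy; best C = argmax, ties to the smallest C."""
    rng = stage_rng(config.seed if seed is None else seed, "cv")
    folds = stratified_folds(y01, config.n_folds, rng)
    Xv = np.asarray(X, dtype=float)
    rows = []
    fold_metrics_by_c = {}
    for c in config.c_grid:
        accs, fold_metrics = [], []
        for i in range(config.n_folds):
            val = folds[i]
            trn = np.concatenate([folds[j] for j in range(config.n_folds) if j != i])
            w, b, f = fit_linear_svm(Xv[trn], y01[trn], c)
            m = evaluate(f(Xv[val]), y01[val])
            accs.append(m["accuracy"])
            fold_metrics.append(m)
        rows.append(dict(c=c, cv_accuracy=float(np.mean(accs))))
        fold_metrics_by_c[c] = fold_metrics
    grid = pd.DataFrame(rows)
    best_i = 0
    for i in range(1, len(grid)):  # strict >: ties keep the smaller C
        if grid["cv_accuracy"].iloc[i] > grid["cv_accuracy"].iloc[best_i]:
            best_i = i
    best_c = float(grid["c"].iloc[best_i])
    return best_c, grid, fold_metrics_by_c[best_c]


def _mean_fold_metrics(fold_metrics: list[dict]) -> tuple[dict, np.ndarray]:
    keys = ("accuracy", "sensitivity", "specificity", "f1", "precision")
    means = {k: float(np.nanmean([m[k] for m in fold_metrics])) for k in keys}
    confusion = np.sum([m["confusion"] for m in fold_metrics], axis=0)
    return means, confusion


def cross_validate_final(table: pd.DataFrame, config: ModelConfig,
                         seed: int | None = None) -> ModelReport:
    """Full procedure: split -> scale -> grid search -> final fit -> test."""
    config.validate()
    y01 = (table[OUTCOME_COLUMN] == config.positive_class).to_numpy().astype(int)
    X = table[list(PREDICTOR_COLUMNS)]
    train_idx, test_idx = split_cohort(y01, config, seed=seed)
    X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
    y_train, y_test = y01[train_idx], y01[test_idx]
    X_train_s, X_test_s, _ = standardize(X_train, X_test, mode=config.leakage_mode)
    best_c, grid, fold_metrics = grid_search_c(X_train_s, y_train, config, seed=seed)
    cv_means, cv_conf = _mean_fold_metrics(fold_metrics)
    w, b, f = fit_linear_svm(X_train_s.to_numpy(), y_train, best_c)
    test_m = evaluate(f(X_test_s.to_numpy()), y_test)
    roc = test_m.pop("roc")
    auc_value = test_m.pop("auc")
    test_conf = test_m.pop("confusion")
    return ModelReport(
        best_c=best_c,
        train_index=train_idx,
        test_index=test_idx,
        cv_metrics=cv_means,
        cv_confusion=cv_conf,
        test_metrics={**test_m, "confusion": test_conf.tolist()},
        roc_points=roc if roc is not None else np.empty((0, 2)),
        auc=auc_value,
        weights=w,
        bias=b,
        feature_names=list(PREDICTOR_COLUMNS),
        grid_results=grid,
        X_train=X_train_s,
        y_train=y_train,
    )
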