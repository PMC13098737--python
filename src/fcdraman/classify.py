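"""Feature selection, SVM training with cross-validated grid search, and
ROC-based evaluation.

The procedure mirrors the study design: 20% of spectra held out before any
training, an L1-penalized linear SVM used purely to rank and select
features, an L2 linear SVM as the final classifier, fivefold stratified
cross-validation over a grid of C and retained-feature counts (scored by
ROC AUC, selection refitted inside every fold so nothing leaks), and the
operating point chosen as the ROC point closest to the upper-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

__all__ = [
    "ModelConfig",
    "EvalReport",
    "split_train_test",
    "select_features_l1",
    "grid_search_cv",
    "fit_final_model",
    "evaluate_on_test",
    "run_model",
]


@dataclass
class ModelConfig:
    """Hyperparameter grid and evaluation protocol."""

    c_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    feature_grid: tuple = (4, 8, 13, 24, 48, 72)
    folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class EvalReport:
    """Held-out evaluation of one binary model."""

    positive_class: str
    roc: pd.DataFrame                 # columns fpr, tpr, threshold
    auc: float
    threshold: float
    confusion: np.ndarray             # [[TP, FN], [FP, TN]]
    sensitivity: float
    specificity: float
    accuracy: float
    best_C: float
    best_n_features: int
    selected_features: list[str]
    train_counts: dict[str, int]
    test_counts: dict[str, int]
    cv_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "auc": float(self.auc),
            "threshold": float(self.threshold),
            "confusion": self.confusion.tolist(),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "accuracy": float(self.accuracy),
            "best_C": float(self.best_C),
            "best_n_features": int(self.best_n_features),
            "selected_features": list(self.selected_features),
            "train_counts": {k: int(v) for k, v in self.train_counts.items()},
            "test_counts": {k: int(v) for k, v in self.test_counts.items()},
            "roc": self.roc.to_dict(orient="list"),
        }


def split_train_test(X: pd.DataFrame, y: pd.Series, test_fraction: float = 0.2,
                     seed: int = 0, stratify_by: str = "class",
                     groups: pd.Series | None = None):
    """Disjoint, exhaustive train/test split set aside before any training.

    ``stratify_by='class'`` preserves class proportions (test size =
    round(fraction * n)); ``stratify_by='patient'`` keeps all spectra of a
    patient on one side (requires ``groups``).
    """
    n_test = int(round(test_fraction * len(X)))
    if stratify_by == "class":
        idx_tr, idx_te = train_test_split(
            np.arange(len(X)), test_size=n_test, random_state=seed, stratify=y.to_numpy())
    elif stratify_by == "patient":
        if groups is None:
            raise ValueError("patient-grouped split requires groups")
        gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        idx_tr, idx_te = next(gss.split(X, y, groups.to_numpy()))
    else:
        raise ValueError(f"unknown stratify_by {stratify_by!r}")
    for side_idx, side in ((idx_tr, "train"), (idx_te, "test")):
        if y.iloc[side_idx].nunique() < y.nunique():
            raise ValueError(f"a class is absent from the {side} side")
    return (X.iloc[idx_tr], y.iloc[idx_tr]), (X.iloc[idx_te], y.iloc[idx_te])


def select_features_l1(X_train: np.ndarray, y_train: np.ndarray,
                       feature_names: Sequence[str], target_count: int,
                       C_selector: float | None = None, seed: int = 0) -> list[str]:
    """Rank features by |coefficient| of an L1-penalized linear SVM and keep
    the top ``target_count``.

    Inputs must already be standardized on the training data. When the L1
    fit at ``C_selector`` zeroes out too many coefficients, the selector
    strength is raised by bisection until at least ``target_count``
    coefficients are nonzero.
    """
    p = X_train.shape[1]
    if target_count > p:
        raise ValueError(f"target_count {target_count} exceeds matrix width {p}")
    if target_count == p:
        return list(feature_names)

    def nonzero_at(C: float) -> np.ndarray:
        svc = LinearSVC(penalty="l1", dual=False, C=C, max_iter=5000,
                        random_state=seed, tol=1e-4)
        svc.fit(X_train, y_train)
        return np.abs(svc.coef_.ravel())

    C = 1.0 if C_selector is None else float(C_selector)
    coefs = nonzero_at(C)
    lo = None
    hi = C
    # Expand upward (weaker penalty) until enough survive, then bisect down.
    tries = 0
    while np.count_nonzero(coefs) < target_count and tries < 20:
        lo, hi = hi, hi * 4.0
        coefs = nonzero_at(hi)
        tries += 1
    order = np.argsort(-coefs, kind="stable")
    return [feature_names[i] for i in order[:target_count]]


def _binary(y: np.ndarray, positive: str) -> np.ndarray:
    return (np.asarray(y) == positive).astype(int)


def grid_search_cv(X: pd.DataFrame, y: pd.Series, positive_class: str,
                   config: ModelConfig) -> tuple[dict, pd.DataFrame]:
    """Cross-validated grid search over (retained features, C).

    Standardization and L1 selection are refitted inside each training fold;
    fold score is the ROC AUC on the held-out fold. Best grid point = highest
    mean AUC, ties broken by fewer features, then smaller C.
    """
    feature_grid = sorted({min(k, X.shape[1]) for k in config.feature_grid})
    yb = _binary(y.to_numpy(), positive_class)
    counts = np.bincount(yb)
    if counts.min() < config.folds:
        raise ValueError("need at least `folds` samples in each class")
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, yb))
    names = list(X.columns)
    rows = []
    for k in feature_grid:
        # Selection depends on the fold, not on C: select once per (fold, k).
        fold_sel = []
        for tr, _te in folds:
            scaler = StandardScaler().fit(X.iloc[tr])
            Xtr = scaler.transform(X.iloc[tr])
            sel = select_features_l1(Xtr, yb[tr], names, k, seed=config.seed)
            fold_sel.append((scaler, [names.index(c) for c in sel]))
        for C in config.c_grid:
            aucs = []
            for (tr, te), (scaler, cols) in zip(folds, fold_sel):
                Xtr = scaler.transform(X.iloc[tr])[:, cols]
                Xte = scaler.transform(X.iloc[te])[:, cols]
                svc = LinearSVC(C=C, max_iter=5000, random_state=config.seed, tol=1e-4)
                svc.fit(Xtr, yb[tr])
                scores = svc.decision_function(Xte)
                fpr, tpr, _ = roc_curve(yb[te], scores)
                aucs.append(float(np.trapezoid(tpr, fpr)))
            rows.append({"n_features": k, "C": C, "mean_auc": float(np.mean(aucs)),
                         "std_auc": float(np.std(aucs))})
    table = pd.DataFrame(rows)
    best = table.sort_values(["mean_auc", "n_features", "C"],
                             ascending=[False, True, True], kind="stable").iloc[0]
    return {"n_features": int(best["n_features"]), "C": float(best["C"])}, table


@dataclass
class FittedModel:
    scaler: StandardScaler
    selected: list[str]
    columns: list[int]
    svc: LinearSVC
    positive_class: str

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.svc.decision_function(self.scaler.transform(X)[:, self.columns])


def fit_final_model(X_train: pd.DataFrame, y_train: pd.Series, positive_class: str,
                    n_features: int, C: float, seed: int = 0) -> FittedModel:
    """Standardize, select and fit the final L2 linear SVM on all train data."""
    yb = _binary(y_train.to_numpy(), positive_class)
    names = list(X_train.columns)
    scaler = StandardScaler().fit(X_train)
    selected = select_features_l1(scaler.transform(X_train), yb, names, n_features, seed=seed)
    cols = [names.index(c) for c in selected]
    svc = LinearSVC(C=C, max_iter=5000, random_state=seed, tol=1e-4)
    svc.fit(scaler.transform(X_train)[:, cols], yb)
    return FittedModel(scaler, selected, cols, svc, positive_class)


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """Full ROC curve (all unique score thresholds plus the +/-inf endpoints)."""
    fpr, tpr, thr = roc_curve(y_true, scores, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate_on_test(model: FittedModel, X_test: pd.DataFrame, y_test: pd.Series,
                     best: Mapping | None = None,
                     train_counts: Mapping[str, int] | None = None,
                     cv_table: pd.DataFrame | None = None) -> EvalReport:
    """ROC evaluation on the held-out set.

    AUC by the trapezoidal rule over the full ROC; the operating point is
    the ROC point minimizing the Euclidean distance to (FPR 0, TPR 1), ties
    resolved toward higher TPR; sensitivity/specificity/accuracy are read
    off the confusion matrix at that threshold with the model's positive
    class as 'positive'.
    """
    yb = _binary(y_test.to_numpy(), model.positive_class)
    if yb.min() == yb.max():
        raise ValueError("test set contains a single class")
    scores = model.decision_scores(X_test)
    roc = roc_points(yb, scores)
    auc = float(np.trapezoid(roc["tpr"], roc["fpr"]))
    d2 = roc["fpr"] ** 2 + (1.0 - roc["tpr"]) ** 2
    # ties -> higher TPR: sort by (distance, -tpr) and take the first
    best_i = roc.assign(d2=d2).sort_values(["d2", "tpr"], ascending=[True, False],
                                           kind="stable").index[0]
    thr = float(roc.loc[best_i, "threshold"])
    pred = (scores >= thr).astype(int)
    tp = int(np.sum((pred == 1) & (yb == 1)))
    fn = int(np.sum((pred == 0) & (yb == 1)))
    fp = int(np.sum((pred == 1) & (yb == 0)))
    tn = int(np.sum((pred == 0) & (yb == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(yb)
    best = best or {}
    return EvalReport(
        positive_class=model.positive_class,
        roc=roc, auc=auc, threshold=thr,
        confusion=np.array([[tp, fn], [fp, tn]]),
        sensitivity=sens, specificity=spec, accuracy=acc,
        best_C=float(best.get("C", np.nan)),
        best_n_features=int(best.get("n_features", len(model.selected))),
        selected_features=list(model.selected),
        train_counts=dict(train_counts or {}),
        test_counts=y_test.value_counts().to_dict(),
        cv_table=cv_table,
    )


def run_model(X: pd.DataFrame, labels: pd.Series, positive_class: str,
              config: ModelConfig | None = None,
              grouping: Mapping[str, str] | None = None,
              stratify_by: str = "class",
              groups: pd.Series | None = None) -> EvalReport:
    """Full procedure for one binary model: (optional label grouping) ->
    split -> grid search on train -> final fit on all train -> held-out
    evaluation.

    ``grouping`` maps raw diagnosis labels to model labels (e.g. both FCD
    subtypes to 'FCDII'); unmapped labels are dropped, which is how the
    subtype model restricts itself to the FCD spectra.
    """
    config = config or ModelConfig()
    y = labels.reindex(X.index)
    if grouping is not None:
        y = y.map(lambda v: grouping.get(v, None))
        keep = y.notna()
        X, y = X.loc[keep], y.loc[keep]
        if groups is not None:
            groups = groups.reindex(X.index)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes after grouping, got {classes}")
    if positive_class not in classes:
        raise ValueError(f"unknown positive_class {positive_class!r} (have {classes})")
    (X_tr, y_tr), (X_te, y_te) = split_train_test(
        X, y, config.test_fraction, config.seed, stratify_by, groups)
    best, table = grid_search_cv(X_tr, y_tr, positive_class, config)
    model = fit_final_model(X_tr, y_tr, positive_class, best["n_features"], best["C"],
                            seed=config.seed)
    return evaluate_on_test(model, X_te, y_te, best,
                            train_counts=y_tr.value_counts().to_dict(), cv_table=table)
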