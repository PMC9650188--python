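"""Feature selection and subject-based leave-one-out classification.

Selection mirrors a two-stage rule: per feature group a random forest is
fit under stratified 10-fold cross-validation at the record level, and
permutation importance (10 random repeats per feature) is computed on each
test fold; importances are averaged over repeats and folds.  The five most
important features of each of the 8 groups become candidates, and only
candidates strictly above the candidate-set median importance are retained
(40 distinct candidates therefore yield exactly 20 features).

Evaluation is leave-one-subject-out (LOSO): all records of one subject
form the test fold.  Held-out predicted probabilities are pooled over
folds to give one ROC/AUC (single-subject folds can be single-class, so a
per-fold AUC is not generally defined).  Grid search maximises pooled AUC.
Per-fold preprocessing (median imputation, z-scoring) is fit on training
rows only; the fit provenance is recorded for leakage auditing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .features import FeatureMatrix, ALL_GROUPS

__all__ = [
    "SelectionResult",
    "EvalReport",
    "FoldProvenance",
    "permutation_importance_by_group",
    "select_features",
    "loso_folds",
    "grid_search",
    "evaluate",
    "DEFAULT_GRID",
]

#: Default hyper-parameter grid for both boosting families.
DEFAULT_GRID = {
    "n_estimators": [50, 100, 150, 200, 300],
    "learning_rate": [0.01, 0.05, 0.1],
    "max_depth": [2, 3, 5],
}


@dataclass
class SelectionResult:
    importances: pd.Series                 # per-feature mean importance
    candidates: dict[str, list[str]]       # per-group top-5 (<=5) lists
    retained: list[str]                    # strictly above candidate median

    @property
    def candidate_list(self) -> list[str]:
        return [c for g in self.candidates.values() for c in g]


@dataclass
class FoldProvenance:
    """Audit record of what was fit where, for one LOSO fold."""

    test_subjects: tuple
    train_subjects: tuple
    fits: dict[str, str] = field(default_factory=dict)  # step -> "train-only"


@dataclass
class EvalReport:
    model_family: str
    mode: str
    params: dict
    accuracy: float        # percent
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: np.ndarray         # (n, 2) fpr, tpr
    importances: pd.Series         # normalized, max = 100
    provenance: list[FoldProvenance] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (metrics, params, ROC, importances)."""
        return {
            "model_family": self.model_family,
            "mode": self.mode,
            "params": self.params,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "roc_points": self.roc_points.tolist(),
            "importances": {k: float(v) for k, v in self.importances.items()},
        }


def _impute_train_medians(
    X_train: pd.DataFrame, X_test: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Median imputation with medians fit on the training rows only."""
    med = X_train.median(axis=0, skipna=True).fillna(0.0)
    return X_train.fillna(med).to_numpy(float), X_test.fillna(med).to_numpy(float)


def permutation_importance_by_group(
    fm: FeatureMatrix,
    group: str,
    seed: int = 0,
    n_splits: int = 10,
    n_repeats: int = 10,
    n_trees: int = 100,
) -> pd.Series:
    """Mean test-fold permutation importance of one feature group.

    Stratified k-fold CV at the record level; per fold a random forest is
    fit on the training rows and permutation importance is computed on the
    held-out rows with ``n_repeats`` random permutations per feature.
    Deterministic for a fixed seed.
    """
    cols = fm.columns_in_group(group)
    if not cols:
        raise ValueError(f"no columns in group {group!r}")
    X = fm.X.loc[:, cols]
    y = fm.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    class_min = np.bincount(y).min()
    if class_min < n_splits:
        raise ValueError(
            f"smallest class has {class_min} records < {n_splits} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    total = np.zeros(len(cols))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = _impute_train_medians(X.iloc[tr], X.iloc[te])
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + fold, n_jobs=1)
        rf.fit(Xtr, y[tr])
        r = permutation_importance(
            rf, Xte, y[te], n_repeats=n_repeats, random_state=seed + fold, n_jobs=1
        )
        total += r.importances_mean
    return pd.Series(total / n_splits, index=cols)


def select_features(
    importances_by_group: dict[str, pd.Series],
    top_k: int = 5,
) -> SelectionResult:
    """Top-5 per group, then strictly-above-median retention.

    Ties in the top-5 ranking break by column order.  With 8 groups of 5
    candidates carrying distinct importances, exactly 20 features survive
    the strict median cut; an all-tied candidate set retains none (warned).
    """
    candidates: dict[str, list[str]] = {}
    for group, imp in importances_by_group.items():
        if len(imp) == 0:
            continue
        order = np.argsort(-imp.to_numpy(), kind="stable")[: min(top_k, len(imp))]
        candidates[group] = [imp.index[i] for i in order]
    cand_cols = [c for g in candidates.values() for c in g]
    if not cand_cols:
        raise ValueError("empty candidate set")
    all_imp = pd.concat(importances_by_group.values())
    cand_imp = all_imp.loc[cand_cols]
    median = float(np.median(cand_imp.to_numpy()))
    retained = [c for c in cand_cols if cand_imp[c] > median]
    if not retained:
        warnings.warn("all candidate importances tied at the median; nothing retained")
    return SelectionResult(importances=all_imp, candidates=candidates, retained=retained)


def run_feature_selection(fm: FeatureMatrix, seed: int = 0, **kwargs) -> SelectionResult:
    """Group-wise permutation importance followed by the retention rule."""
    groups = [g for g in ALL_GROUPS if fm.columns_in_group(g)]
    imps = {g: permutation_importance_by_group(fm, g, seed=seed, **kwargs) for g in groups}
    return select_features(imps)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) in percent, MCI = positive class.

    Precision is NaN (warned) when nothing is predicted positive; F1 is the
    harmonic mean of precision and recall.
    """
    total = tp + fp + fn + tn
    accuracy = 100.0 * (tp + tn) / total if total else float("nan")
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision undefined")
        precision = float("nan")
    else:
        precision = 100.0 * tp / (tp + fp)
    recall = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0
        else float("nan")
    )
    return accuracy, precision, recall, f1


def loso_folds(subject_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds over record-level subject IDs.

    One fold per subject (order of first appearance); train and test
    subject sets are disjoint in every fold and the test sets partition
    the records.
    """
    sids = np.asarray(subject_ids)
    subjects = list(dict.fromkeys(sids.tolist()))
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    folds = []
    for s in subjects:
        te = np.flatnonzero(sids == s)
        tr = np.flatnonzero(sids != s)
        folds.append((tr, te))
    return folds


def _make_model(family: str, params: dict, seed: int):
    if family == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "xgboost":
        return XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            # exact splits put thresholds midway between neighbouring
            # training values; hist's binned thresholds sit on data points,
            # which misplaces held-out samples on these small matrices
            tree_method="exact",
            n_jobs=1,
            **params,
        )
    raise ValueError(f"unknown model family {family!r}")


def _balanced_weights(y: np.ndarray) -> np.ndarray:
    """Class-balanced sample weights.

    LOSO folds have slightly different training priors (removing one
    subject's records shifts the class mix), and boosted models track that
    prior; pooled over folds this produces a spurious anti-correlation
    between held-out probabilities and labels.  Balancing the training
    weights pins the no-information prediction at 0.5 in every fold, so
    pooled ROC analysis reflects signal, not fold composition.
    """
    counts = np.bincount(y, minlength=2).astype(float)
    w = len(y) / (2.0 * counts[y])
    return w


def _pooled_predictions(
    family: str,
    params: dict,
    fm: FeatureMatrix,
    folds,
    seed: int,
    columns: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[FoldProvenance]]:
    """Held-out probabilities pooled over folds, aligned to record order."""
    cols = list(columns) if columns is not None else list(fm.X.columns)
    X = fm.X.loc[:, cols]
    y = fm.y
    proba = np.full(len(y), np.nan)
    provenance = []
    for tr, te in folds:
        Xtr, Xte = _impute_train_medians(X.iloc[tr], X.iloc[te])
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        model = _make_model(family, params, seed)
        model.fit(Xtr, y[tr], sample_weight=_balanced_weights(y[tr]))
        proba[te] = model.predict_proba(Xte)[:, 1]
        provenance.append(
            FoldProvenance(
                test_subjects=tuple(np.unique(fm.subject_ids[te])),
                train_subjects=tuple(np.unique(fm.subject_ids[tr])),
                fits={"imputation_medians": "train-only", "zscore_params": "train-only"},
            )
        )
    return proba, y, provenance


def grid_search(
    model_family: str,
    grid: dict[str, list],
    fm: FeatureMatrix,
    folds,
    seed: int = 0,
    columns: list[str] | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Pooled-LOSO-AUC grid search; ties break by grid order.

    Returns (best parameter dict, table of all grid points with AUC).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    keys = list(grid)
    rows = []
    best, best_auc = None, -np.inf
    from itertools import product

    for values in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        proba, y, _ = _pooled_predictions(model_family, params, fm, folds, seed, columns)
        if len(np.unique(y)) < 2:
            raise ValueError("pooled labels are degenerate")
        auc = roc_auc_score(y, proba)
        rows.append({**params, "auc": auc})
        if auc > best_auc:
            best_auc, best = auc, params
    return best, pd.DataFrame(rows)


def permuted_label_auc(
    model_family: str,
    params: dict,
    fm: FeatureMatrix,
    folds,
    n_permutations: int = 10,
    seed: int = 0,
    columns: list[str] | None = None,
) -> float:
    """No-signal control: mean pooled LOSO AUC under subject-level label
    permutation.

    Labels are permuted at the subject level (all records of a subject keep
    a common, randomly reassigned label) so the subject-clustering structure
    of the records is preserved.  The mean over permutations estimates the
    centre of the null AUC distribution; pooled leave-one-out AUC is known
    to be mildly pessimistic at small n, so values a little below 0.5 are
    expected even with a perfectly indifferent classifier.
    """
    rng = np.random.default_rng(seed)
    subjects = list(dict.fromkeys(np.asarray(fm.subject_ids).tolist()))
    subj_label = {s: int(fm.y[fm.subject_ids == s][0]) for s in subjects}
    labels = np.array([subj_label[s] for s in subjects])
    aucs = []
    for _ in range(n_permutations):
        mapping = dict(zip(subjects, rng.permutation(labels)))
        y_perm = np.array([mapping[s] for s in fm.subject_ids])
        fm_perm = FeatureMatrix(
            X=fm.X, y=y_perm, subject_ids=fm.subject_ids, mode=fm.mode,
            group_of=dict(fm.group_of),
        )
        proba, y, _ = _pooled_predictions(model_family, params, fm_perm, folds, seed, columns)
        aucs.append(roc_auc_score(y, proba))
    return float(np.mean(aucs))


def evaluate(
    model_family: str,
    best_params: dict,
    fm: FeatureMatrix,
    folds,
    seed: int = 0,
    threshold: float = 0.5,
    columns: list[str] | None = None,
) -> EvalReport:
    """Pooled LOSO evaluation at the 0.5 probability threshold.

    MCI is the positive class.  Accuracy/precision/recall/F1 are reported
    in percent; AUC from pooled probabilities; feature importances come
    from a final refit on all records, rescaled so the maximum is 100.
    """
    proba, y, provenance = _pooled_predictions(
        model_family, best_params, fm, folds, seed, columns
    )
    pred = (proba >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    accuracy, precision, recall, f1 = confusion_metrics(tp, fp, fn, tn)
    auc = 100.0 * roc_auc_score(y, proba)
    fpr, tpr, _ = roc_curve(y, proba)

    cols = list(columns) if columns is not None else list(fm.X.columns)
    X_all = fm.X.loc[:, cols]
    med = X_all.median(axis=0, skipna=True).fillna(0.0)
    final = _make_model(model_family, best_params, seed)
    final.fit(X_all.fillna(med).to_numpy(float), y, sample_weight=_balanced_weights(y))
    raw_imp = np.asarray(final.feature_importances_, dtype=float)
    top = raw_imp.max()
    norm = 100.0 * raw_imp / top if top > 0 else raw_imp
    return EvalReport(
        model_family=model_family,
        mode=fm.mode,
        params=dict(best_params),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc,
        roc_points=np.stack([fpr, tpr], axis=1),
        importances=pd.Series(norm, index=cols),
        provenance=provenance,
    )
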