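"""Sequential forward selection (SFS) with a cross-validated criterion.

Greedy top-down dimensionality reduction: starting from the empty set, each
step adds the feature that maximizes the cross-validated score of the
enlarged subset.  Ties break toward the lowest column index; the fold
assignment (derived from the seed) is the only stochastic element, so a
given (data, seed) pair always reproduces the same selection.

Features are z-scored inside each training fold, with the fold's scaling
applied to its validation part, so no information leaks across folds.
Scoring is 10-fold CV accuracy of the classifier for classification tasks
and 10-fold CV R² of a PLSR for quantification tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import config_context as sklearn_config
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = ["SelectionResult", "sfs_select", "make_default_estimator"]


@dataclass
class SelectionResult:
    """Ordered selected features with the forward-search score path."""

    selected: list[int]
    scores: list[float]
    criterion: str
    seed: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def selected_names(self) -> list[str]:
        if not self.feature_names:
            return [str(i) for i in self.selected]
        return [self.feature_names[i] for i in self.selected]

    def to_dict(self) -> dict:
        return {
            "selected": self.selected_names,
            "selected_indices": list(map(int, self.selected)),
            "scores": list(map(float, self.scores)),
            "criterion": self.criterion,
            "seed": int(self.seed),
        }


def make_default_estimator(task: str, kernel: str = "quadratic"):
    """Default criterion estimator: an SVM for classification, PLSR for
    regression; mirrors the downstream evaluation heads."""
    if task == "classification":
        if kernel == "linear":
            return SVC(kernel="linear", C=1.0)
        if kernel == "quadratic":
            return SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0)
        raise ValueError(f"unsupported kernel {kernel!r}")
    if task == "regression":
        return PLSRegression(n_components=1, scale=False)
    raise ValueError(f"unsupported task {task!r}")


def _fold_standardized(X: np.ndarray, y: np.ndarray, task: str, folds: int, seed: int):
    """Per-fold (train, test) views of X z-scored with train-fold statistics."""
    if task == "classification":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    prepared = []
    for tr, te in splitter.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        prepared.append(((X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd, y[te]))
    return prepared


def _cv_score(prepared, cols: list[int], estimator, task: str, base_components: int = 1) -> float:
    # refits one estimator instance per eval; sklearn fit() resets state
    scores = []
    for X_tr, y_tr, X_te, y_te in prepared:
        if isinstance(estimator, PLSRegression):
            estimator.set_params(
                n_components=min(base_components, len(cols), len(y_tr) - 1)
            )
        estimator.fit(X_tr[:, cols], y_tr)
        if task == "classification":
            scores.append(np.mean(estimator.predict(X_te[:, cols]) == y_te))
        else:
            pred = np.ravel(estimator.predict(X_te[:, cols]))
            ss_res = np.sum((y_te - pred) ** 2)
            ss_tot = np.sum((y_te - y_te.mean()) ** 2)
            scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return float(np.mean(scores))


def sfs_select(
    X: np.ndarray,
    y,
    k: int,
    task: str = "classification",
    estimator=None,
    folds: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
    kernel: str = "quadratic",
) -> SelectionResult:
    """Greedy forward selection of ``k`` features maximizing the CV criterion.

    Parameters
    ----------
    X : (n_obs, n_features) feature matrix.
    y : class labels (classification) or numeric targets (regression).
    k : number of features to select (1 <= k <= n_features).
    task : "classification" (CV accuracy) or "regression" (CV R²).
    estimator : optional sklearn estimator overriding the default criterion.
    folds, seed : CV fold count and shuffling seed (the only randomness).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {X.shape[1]}")
    if task == "classification":
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("classification needs at least two classes")
        if counts.min() < folds:
            raise ValueError(
                f"smallest class has {counts.min()} members < {folds} folds"
            )
    else:
        y = y.astype(float)

    estimator = estimator or make_default_estimator(task, kernel)
    prepared = _fold_standardized(X, y, task, folds, seed)

    work_est = clone(estimator)
    base_components = (
        work_est.n_components if isinstance(work_est, PLSRegression) else 1
    )
    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(X.shape[1]))
    with sklearn_config(assume_finite=True):
        for _ in range(k):
            best_j, best_score = None, -np.inf
            for j in remaining:  # ascending index order -> lowest-index tie-break
                s = _cv_score(prepared, selected + [j], work_est, task, base_components)
                if s > best_score:
                    best_j, best_score = j, s
            selected.append(best_j)
            scores.append(best_score)
            remaining.remove(best_j)
    return SelectionResult(
        selected=selected,
        scores=scores,
        criterion=f"{folds}-fold CV {'accuracy' if task == 'classification' else 'R2'} "
        f"({type(estimator).__name__})",
        seed=seed,
        feature_names=list(feature_names) if feature_names is not None else [],
    )
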