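"""Evaluation heads: LDA projection, cross-validated SVM classification,
and PLSR concentration calibration.

Three models, matching the roles they play in virtual-e-nose analysis:

* LDA projects the selected feature space onto at most (classes − 1)
  discriminant functions for visual class separation.
* A stratified 10-fold cross-validated SVM (quadratic polynomial kernel by
  default, linear available) yields out-of-fold predictions, a confusion
  matrix and per-class correct-classification rates.  Each gas group pools
  all its concentrations.  The same head re-used with concentration levels
  as classes gives per-gas concentration classification.
* PLSR calibrates features to concentration (ppb): an 80/20 stratified
  split, fold-wise CV on the training part to pick the number of latent
  components (one-standard-error rule), and RMSE / R² on the held-out 20%.

Feature z-scoring is always learned on training data only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_predict, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassificationReport",
    "LDAScores",
    "QuantificationReport",
    "lda_fit_project",
    "svm_crossval",
    "per_gas_concentration_classifier",
    "plsr_quantify",
    "compute_metrics",
]

log = logging.getLogger(__name__)


def compute_metrics(true, predicted) -> tuple[float, float]:
    """(RMSE, R²) with R² = 1 − SS_res/SS_tot; errors on zero-variance truth."""
    t = np.asarray(true, float)
    p = np.asarray(predicted, float)
    if t.shape != p.shape or t.size < 2:
        raise ValueError("true and predicted must have equal length >= 2")
    ss_tot = np.sum((t - t.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined for zero-variance truth")
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))
    r2 = float(1.0 - np.sum((t - p) ** 2) / ss_tot)
    return rmse, r2


def _make_svc(kernel: str) -> SVC:
    # one-vs-one multi-class (sklearn SVC default)
    if kernel == "linear":
        return SVC(kernel="linear", C=1.0)
    if kernel == "quadratic":
        return SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0)
    raise ValueError(f"unsupported kernel {kernel!r}; use 'linear' or 'quadratic'")


@dataclass
class ClassificationReport:
    """Out-of-fold confusion matrix and derived rates."""

    classes: list
    counts: np.ndarray          # true x predicted
    kernel: str
    folds: int
    seed: int

    @property
    def row_percent(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        return self.counts / totals * 100.0

    @property
    def per_class_rate_pct(self) -> dict:
        return {c: float(r) for c, r in zip(self.classes, np.diag(self.row_percent))}

    @property
    def accuracy_pct(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum() * 100.0)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "counts": self.counts.tolist(),
            "row_percent": self.row_percent.round(4).tolist(),
            "per_class_rate_pct": {str(k): v for k, v in self.per_class_rate_pct.items()},
            "accuracy_pct": self.accuracy_pct,
            "kernel": self.kernel,
            "folds": self.folds,
            "seed": self.seed,
        }


@dataclass
class LDAScores:
    """Observations projected onto discriminant functions DF1..DFd."""

    scores: pd.DataFrame  # columns DF1..DFd + label

    @property
    def n_functions(self) -> int:
        return sum(c.startswith("DF") for c in self.scores.columns)


@dataclass
class QuantificationReport:
    """Held-out predicted-vs-true concentrations with RMSE and R²."""

    true_ppb: np.ndarray
    predicted_ppb: np.ndarray
    r2: float
    rmse_ppb: float
    n_components: int
    n_train: int
    n_test: int
    seed: int
    gas: str = ""
    cv_rmse_path: list[float] = field(default_factory=list)

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"true_ppb": self.true_ppb, "predicted_ppb": self.predicted_ppb})

    def to_dict(self) -> dict:
        return {
            "gas": self.gas,
            "r2": self.r2,
            "rmse_ppb": self.rmse_ppb,
            "n_components": self.n_components,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
            "true_ppb": self.true_ppb.tolist(),
            "predicted_ppb": self.predicted_ppb.tolist(),
        }


def lda_fit_project(X: np.ndarray, y) -> LDAScores:
    """Project z-scored features onto <= (classes − 1) discriminant axes.

    Falls back to a shrinkage (eigen-solver) LDA when the within-class
    scatter is singular; the fallback is logged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    Xz = StandardScaler().fit_transform(X)
    d = min(len(classes) - 1, X.shape[1])
    lda = LinearDiscriminantAnalysis(solver="svd", n_components=d)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            proj = lda.fit_transform(Xz, y)
    except (np.linalg.LinAlgError, UserWarning):
        log.warning("within-class scatter singular/collinear; using shrinkage LDA")
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto", n_components=d)
        proj = lda.fit_transform(Xz, y)
    df = pd.DataFrame(proj, columns=[f"DF{i + 1}" for i in range(proj.shape[1])])
    df["label"] = y
    return LDAScores(scores=df)


def svm_crossval(
    X: np.ndarray,
    y,
    kernel: str = "quadratic",
    folds: int = 10,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold cross-validated SVM classification.

    Out-of-fold predictions populate the confusion matrix; z-scoring is fit
    inside each training fold.  Every class must have at least ``folds``
    members.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )
    pipe = Pipeline([("scale", StandardScaler()), ("svc", _make_svc(kernel))])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(pipe, X, y, cv=cv)
    counts_mat = confusion_matrix(y, pred, labels=classes)
    return ClassificationReport(
        classes=list(classes), counts=counts_mat, kernel=kernel, folds=folds, seed=seed
    )


def per_gas_concentration_classifier(
    X: np.ndarray,
    conc_ppb,
    kernel: str = "quadratic",
    folds: int = 10,
    seed: int = 0,
) -> ClassificationReport:
    """Concentration-level classification for a single gas.

    Same contract as :func:`svm_crossval` with the distinct concentration
    values as classes.
    """
    levels = np.asarray(conc_ppb, float)
    if len(np.unique(levels)) < 2:
        raise ValueError("need at least two concentration levels")
    labels = np.array([f"{c:g}" for c in levels])
    rep = svm_crossval(X, labels, kernel=kernel, folds=folds, seed=seed)
    # present classes in numeric level order rather than lexicographic
    order = np.argsort([float(c) for c in rep.classes])
    rep.classes = [rep.classes[i] for i in order]
    rep.counts = rep.counts[np.ix_(order, order)]
    return rep


def plsr_quantify(
    X: np.ndarray,
    conc_ppb,
    n_components: int | None = None,
    folds: int = 10,
    split_seed: int = 0,
    test_size: float = 0.2,
    max_components: int = 10,
    gas: str = "",
) -> QuantificationReport:
    """PLSR concentration calibration with an 80/20 evaluation split.

    The split is stratified by concentration level; ``n_components`` is
    chosen on the training part by fold-wise CV RMSE (smallest model within
    one standard error of the optimum) unless given explicitly.  RMSE and R²
    are reported on the held-out test part.
    """
    X = np.asarray(X, float)
    y = np.asarray(conc_ppb, float)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    strata = np.array([f"{c:g}" for c in y])
    # stratify only if every level can appear in both parts
    _, lvl_counts = np.unique(strata, return_counts=True)
    strat = strata if lvl_counts.min() >= 2 else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=split_seed, stratify=strat
    )
    scaler = StandardScaler().fit(X_tr)
    X_trz, X_tez = scaler.transform(X_tr), scaler.transform(X_te)

    rank_cap = int(min(max_components, np.linalg.matrix_rank(X_trz), len(y_tr) - 2))
    if rank_cap < 1:
        raise ValueError("training data has insufficient rank for PLSR")
    cv_rmse_path: list[float] = []
    if n_components is None:
        kf = KFold(n_splits=min(folds, len(y_tr)), shuffle=True, random_state=split_seed)
        cv_stats = []
        for m in range(1, rank_cap + 1):
            fold_rmse = []
            for tr, va in kf.split(X_trz):
                pls = PLSRegression(n_components=m, scale=False)
                pls.fit(X_trz[tr], y_tr[tr])
                pred = np.ravel(pls.predict(X_trz[va]))
                fold_rmse.append(np.sqrt(np.mean((y_tr[va] - pred) ** 2)))
            cv_stats.append((np.mean(fold_rmse), np.std(fold_rmse) / np.sqrt(len(fold_rmse))))
        cv_rmse_path = [float(m) for m, _ in cv_stats]
        best = int(np.argmin([m for m, _ in cv_stats]))
        threshold = cv_stats[best][0] + cv_stats[best][1]
        n_components = next(
            m + 1 for m, (mean_rmse, _) in enumerate(cv_stats) if mean_rmse <= threshold
        )
    elif n_components > rank_cap:
        raise ValueError(f"n_components={n_components} exceeds usable rank {rank_cap}")

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X_trz, y_tr)
    pred = np.ravel(pls.predict(X_tez))
    rmse, r2 = compute_metrics(y_te, pred)
    return QuantificationReport(
        true_ppb=y_te,
        predicted_ppb=pred,
        r2=r2,
        rmse_ppb=rmse,
        n_components=int(n_components),
        n_train=len(y_tr),
        n_test=len(y_te),
        seed=split_seed,
        gas=gas,
        cv_rmse_path=cv_rmse_path,
    )
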