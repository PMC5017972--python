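"""PCA feature selection and linear-SVM classification.

The protocol mirrors the published evaluation: features are standardised
(training-fold statistics only), projected onto the leading principal
components (explicit k or a 95% explained-variance rule), and separated by a
soft-margin linear SVM.  Evaluation is two-fold: the cohort is split into
two stratified halves, each half is used once for training and once for
testing, and predictions are pooled — no test-fold information ever enters
the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

LABELS = ("glaucoma", "healthy")


@dataclass
class FoldPlan:
    """Stratified assignment of each sample to fold 1 or 2."""

    assignment: np.ndarray        # int array of 1s and 2s
    seed: int

    @classmethod
    def stratified(cls, labels, seed: int = 0) -> "FoldPlan":
        labels = np.asarray(labels)
        rng = np.random.default_rng(seed)
        assignment = np.zeros(len(labels), dtype=int)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            idx = rng.permutation(idx)
            half = (len(idx) + 1) // 2
            assignment[idx[:half]] = 1
            assignment[idx[half:]] = 2
        return cls(assignment, seed)

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment)
        if not np.isin(a, (1, 2)).all():
            raise ValueError("fold assignment must be 1 or 2 everywhere")
        self.assignment = a


# ----------------------------------------------------------------------
# PCA


def pca_fit_transform(X: np.ndarray, k: int | None = None,
                      variance_target: float = 0.95):
    """Centre X and project on the top-k covariance eigendirections.

    Returns ``(mean, components (k×d), explained_ratio, X_k)``.  Sign
    convention: each component's largest-magnitude coordinate is positive,
    so the basis is reproducible across BLAS builds.
    """
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if k is not None and k > d:
        raise ValueError(f"k={k} exceeds feature dimension {d}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evals = s ** 2 / max(1, n - 1)
    total = evals.sum()
    if k is None:
        if total <= 0:
            k = 1
        else:
            cum = np.cumsum(evals) / total
            k = int(np.searchsorted(cum, variance_target) + 1)
        k = min(k, Vt.shape[0])
    comps = Vt[:k].copy()
    for row in comps:                      # deterministic sign
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    ratio = float(evals[:k].sum() / total) if total > 0 else 1.0
    return mean, comps, ratio, Xc @ comps.T


# ----------------------------------------------------------------------
# SVM


def svm_train_linear(X: np.ndarray, y, C: float = 1.0) -> SVC:
    """Soft-margin linear SVM; deterministic for a fixed input order."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(np.asarray(X, dtype=np.float64), y)
    return clf


@dataclass
class ClassifierBundle:
    """Frozen standardise -> PCA -> linear-SVM pipeline."""

    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    pca_mean: np.ndarray
    pca_basis: np.ndarray          # k×d'
    svm_weights: np.ndarray        # k
    svm_bias: float
    classes: tuple[str, str]       # decision > 0 -> classes[1]
    k: int = 0
    explained_variance: float = 1.0

    def __post_init__(self) -> None:
        self.k = int(self.pca_basis.shape[0])
        gram = self.pca_basis @ self.pca_basis.T
        if np.abs(gram - np.eye(self.k)).max() > 1e-8:
            raise ValueError("PCA basis is not orthonormal")

    def _project(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64) - self.scaler_mean) / self.scaler_sd
        return (Z - self.pca_mean) @ self.pca_basis.T

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._project(X) @ self.svm_weights + self.svm_bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        dec = self.decision_function(X)
        return np.where(dec > 0, self.classes[1], self.classes[0])

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "pca_basis": self.pca_basis.tolist(),
            "svm_weights": self.svm_weights.tolist(),
            "svm_bias": self.svm_bias,
            "classes": list(self.classes),
            "explained_variance": self.explained_variance,
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierBundle":
        d = json.loads(Path(path).read_text())
        return cls(
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_sd=np.array(d["scaler_sd"]),
            pca_mean=np.array(d["pca_mean"]),
            pca_basis=np.array(d["pca_basis"]),
            svm_weights=np.array(d["svm_weights"]),
            svm_bias=float(d["svm_bias"]),
            classes=tuple(d["classes"]),
            explained_variance=float(d["explained_variance"]),
        )


def train_classifier(X: np.ndarray, y, k: int | None = None,
                     variance_target: float = 0.95,
                     C: float = 1.0) -> ClassifierBundle:
    """Fit the full pipeline on a training set."""
    X = np.asarray(X, dtype=np.float64)
    sm = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - sm) / sd
    pmean, basis, ratio, Zk = pca_fit_transform(Z, k, variance_target)
    clf = svm_train_linear(Zk, y, C)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    return ClassifierBundle(sm, sd, pmean, basis, w, b,
                            classes=tuple(clf.classes_),
                            explained_variance=ratio)


def two_fold_evaluate(X: np.ndarray, y, plan: FoldPlan | None = None,
                      k: int | None = None, variance_target: float = 0.95,
                      C: float = 1.0, seed: int = 0):
    """Train on each fold, test on the other, pool the predictions.

    Returns ``(ConfusionTable, predictions)`` with one prediction per
    sample.  Raises if either fold ends up single-class.
    """
    from .fusion import ConfusionTable   # late import avoids a module cycle
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if plan is None:
        plan = FoldPlan.stratified(y, seed)
    a = plan.assignment
    if len(a) != len(y):
        raise ValueError("fold plan does not cover the samples")
    preds = np.empty(len(y), dtype=object)
    for train_fold, test_fold in ((1, 2), (2, 1)):
        tr = a == train_fold
        te = a == test_fold
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {train_fold} contains a single class")
        bundle = train_classifier(X[tr], y[tr], k, variance_target, C)
        preds[te] = bundle.predict(X[te])
    preds = preds.astype(str)
    return ConfusionTable.from_predictions(y, preds), preds
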