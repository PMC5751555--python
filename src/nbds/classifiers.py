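"""Representation-based classifiers: ProCRC, CRC, SRC, and k-NN.

Given a training dictionary ``S = [S_1, ..., S_K]`` (samples as columns,
one partition per class) and a test vector ``t``, the probabilistic
collaborative representation classifier (ProCRC) solves

    A* = argmin_A  ||t - S A||_2^2 + lam ||A||_2^2
                   + (gamma / K) * sum_k ||S A - S_k A_k||_2^2

and labels ``t`` with the class of smallest residual ||S A* - S_k A*_k||_2.
Writing M_k for the 0/1 diagonal selector of class-k columns, the normal
equations give the closed form

    [S'S + lam I + (gamma/K) sum_k (I - M_k) S'S (I - M_k)] A = S' t,

so classification of any number of test vectors reuses one Cholesky
factorization.  CRC is the gamma = 0 ridge special case with the classic
regularized residual ||t - S_k A_k|| / ||A_k||; SRC replaces the l2 penalty
with l1 (solved by FISTA); k-NN is the usual Euclidean-vote baseline.  All
tie-breaks go to the lowest class index, making every classifier
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import InputValidationError, NumericalError
from .types import LabeledDataset

__all__ = [
    "ProCRClassifier",
    "CRClassifier",
    "SRClassifier",
    "KNearestClassifier",
    "LinearMarginClassifier",
    "ClassificationResult",
    "fit_procrc",
    "classify_procrc",
    "fit_classify_crc",
    "fit_classify_src",
    "fit_classify_knn",
    "make_classifier",
]


@dataclass
class ClassificationResult:
    """Predicted label with per-class residuals and the solved coefficients."""

    label: object
    residuals: np.ndarray  # (K,)
    coefficients: np.ndarray | None  # (n,) or None for k-NN


class _RepresentationBase(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing; samples as rows at the sklearn surface."""

    def _store_training(self, X, y, normalize: bool):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InputValidationError("X must be (n_samples, n_features) matching y")
        if not np.all(np.isfinite(X)):
            raise InputValidationError("training features contain non-finite values")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 1:
            raise InputValidationError("need at least one class")
        S = X.T.copy()  # columns are samples
        if normalize:
            norms = np.linalg.norm(S, axis=0)
            norms[norms == 0] = 1.0
            S = S / norms
        self.S_ = S
        self.y_ = y
        self.class_masks_ = [y == c for c in self.classes_]
        self.n_features_in_ = X.shape[1]
        return S

    def _validate_test(self, X):
        check_is_fitted(self, "S_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise InputValidationError(
                f"test dimension {X.shape[1]} != training dimension "
                f"{self.n_features_in_}"
            )
        if getattr(self, "normalize", False):
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            X = X / norms
        return X

    def residuals(self, X) -> np.ndarray:
        """Per-class residual matrix, shape (n_samples, K)."""
        raise NotImplementedError

    def predict(self, X):
        res = self.residuals(X)
        # argmin returns the first minimum: ties go to the lowest class index
        return self.classes_[np.argmin(res, axis=1)]

    def classify_one(self, t) -> ClassificationResult:
        t = np.asarray(t, dtype=float).reshape(1, -1)
        res = self.residuals(t)[0]
        coef = self.coefficients(t)[0] if hasattr(self, "coefficients") else None
        return ClassificationResult(
            label=self.classes_[int(np.argmin(res))], residuals=res, coefficients=coef
        )


class ProCRClassifier(_RepresentationBase):
    """Probabilistic collaborative representation classifier.

    Parameters
    ----------
    lam : float
        Ridge penalty on the representation coefficients (lambda >= 0).
    gamma : float
        Class-consistency penalty weight (gamma >= 0).
    normalize : bool
        Scale training columns (and test vectors) to unit Euclidean norm.
    residual_rule : {"consistency", "reconstruction"}
        ``consistency`` is the printed rule ||S A - S_k A_k||; the
        alternative is the classic ||t - S_k A_k|| reconstruction residual.
    """

    def __init__(self, lam: float = 0.7, gamma: float = 0.001,
                 normalize: bool = True, residual_rule: str = "consistency"):
        self.lam = lam
        self.gamma = gamma
        self.normalize = normalize
        self.residual_rule = residual_rule

    def fit(self, X, y):
        if self.lam < 0 or self.gamma < 0:
            raise InputValidationError("lam and gamma must be non-negative")
        if self.residual_rule not in ("consistency", "reconstruction"):
            raise InputValidationError(
                f"unknown residual rule {self.residual_rule!r}"
            )
        S = self._store_training(X, y, self.normalize)
        n = S.shape[1]
        K = len(self.classes_)
        G = S.T @ S
        P = G + self.lam * np.eye(n)
        for mask in self.class_masks_:
            # (I - M_k) G (I - M_k): zero out the class-k rows and columns
            Gk = G.copy()
            Gk[mask, :] = 0.0
            Gk[:, mask] = 0.0
            P += (self.gamma / K) * Gk
        try:
            self._chol = linalg.cho_factor(P)
        except linalg.LinAlgError as exc:
            raise NumericalError(
                "normal-equation matrix is singular; set lam > 0"
            ) from exc
        if not np.all(np.isfinite(self._chol[0])):
            raise NumericalError(
                "normal-equation matrix is numerically singular; set lam > 0"
            )
        return self

    def coefficients(self, X) -> np.ndarray:
        """Closed-form minimizers, one row per test sample, shape (n_test, n)."""
        X = self._validate_test(X)
        return linalg.cho_solve(self._chol, self.S_.T @ X.T).T

    def residuals(self, X) -> np.ndarray:
        X = self._validate_test(X)
        A = linalg.cho_solve(self._chol, self.S_.T @ X.T)  # (n, n_test)
        SA = self.S_ @ A
        out = np.empty((X.shape[0], len(self.classes_)))
        for k, mask in enumerate(self.class_masks_):
            Sk_Ak = self.S_[:, mask] @ A[mask, :]
            if self.residual_rule == "consistency":
                out[:, k] = np.linalg.norm(SA - Sk_Ak, axis=0)
            else:
                out[:, k] = np.linalg.norm(X.T - Sk_Ak, axis=0)
        return out


class CRClassifier(_RepresentationBase):
    """Collaborative representation classifier (ridge representation).

    Solves ``argmin_A ||t - S A||^2 + lam ||A||^2`` and scores class k by the
    regularized residual ``||t - S_k A_k|| / ||A_k||``.
    """

    def __init__(self, lam: float = 0.01, normalize: bool = True):
        self.lam = lam
        self.normalize = normalize

    def fit(self, X, y):
        if self.lam < 0:
            raise InputValidationError("lam must be non-negative")
        S = self._store_training(X, y, self.normalize)
        n = S.shape[1]
        try:
            self._chol = linalg.cho_factor(S.T @ S + self.lam * np.eye(n))
        except linalg.LinAlgError as exc:
            raise NumericalError(
                "normal-equation matrix is singular; set lam > 0"
            ) from exc
        return self

    def coefficients(self, X) -> np.ndarray:
        X = self._validate_test(X)
        return linalg.cho_solve(self._chol, self.S_.T @ X.T).T

    def residuals(self, X) -> np.ndarray:
        X = self._validate_test(X)
        A = linalg.cho_solve(self._chol, self.S_.T @ X.T)
        out = np.empty((X.shape[0], len(self.classes_)))
        with np.errstate(divide="ignore", invalid="ignore"):
            for k, mask in enumerate(self.class_masks_):
                rec = np.linalg.norm(X.T - self.S_[:, mask] @ A[mask, :], axis=0)
                norm_ak = np.linalg.norm(A[mask, :], axis=0)
                out[:, k] = np.where(norm_ak > 0, rec / norm_ak, np.inf)
        return out


def _soft_threshold(v: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)


class SRClassifier(_RepresentationBase):
    """Sparse representation classifier (l1-penalized least squares).

    Solves ``argmin_A ||t - S A||^2 + lam ||A||_1`` with FISTA (accelerated
    iterative soft-thresholding) to the configured tolerance, and scores
    class k by the reconstruction residual ``||t - S_k A_k||``.
    """

    def __init__(self, lam: float = 0.1, normalize: bool = True,
                 tol: float = 1e-6, max_iter: int = 20000):
        self.lam = lam
        self.normalize = normalize
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.lam < 0:
            raise InputValidationError("lam must be non-negative")
        S = self._store_training(X, y, self.normalize)
        self._lipschitz = 2.0 * np.linalg.norm(S, ord=2) ** 2
        return self

    def _solve_one(self, t: np.ndarray) -> np.ndarray:
        S = self.S_
        n = S.shape[1]
        step = 1.0 / max(self._lipschitz, 1e-12)
        A = np.zeros(n)
        Z = A.copy()
        momentum = 1.0
        for it in range(self.max_iter):
            grad = 2.0 * (S.T @ (S @ Z - t))
            A_new = _soft_threshold(Z - step * grad, step * self.lam)
            momentum_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * momentum**2))
            Z = A_new + ((momentum - 1.0) / momentum_new) * (A_new - A)
            delta = np.max(np.abs(A_new - A))
            A, momentum = A_new, momentum_new
            if delta < self.tol:
                return A
        raise NumericalError(
            f"FISTA did not converge in {self.max_iter} iterations "
            f"(last step change {delta:.2e}, tol {self.tol:.0e})"
        )

    def coefficients(self, X) -> np.ndarray:
        X = self._validate_test(X)
        return np.stack([self._solve_one(t) for t in X])

    def residuals(self, X) -> np.ndarray:
        X = self._validate_test(X)
        out = np.empty((X.shape[0], len(self.classes_)))
        for i, t in enumerate(X):
            A = self._solve_one(t)
            for k, mask in enumerate(self.class_masks_):
                out[i, k] = np.linalg.norm(t - self.S_[:, mask] @ A[mask])
        return out


class KNearestClassifier(_RepresentationBase):
    """k-nearest-neighbor baseline with deterministic tie handling.

    Neighbors are found by exact Euclidean distance (stable sort, so equal
    distances resolve to the earliest training column); vote ties resolve to
    the lowest class index.
    """

    def __init__(self, k: int = 1, normalize: bool = False):
        self.k = k
        self.normalize = normalize

    def fit(self, X, y):
        if self.k < 1:
            raise InputValidationError("k must be at least 1")
        S = self._store_training(X, y, self.normalize)
        if self.k > S.shape[1]:
            raise InputValidationError("k exceeds the number of training samples")
        return self

    def residuals(self, X) -> np.ndarray:
        """Negative vote counts, so predict's argmin picks the majority class."""
        X = self._validate_test(X)
        d2 = (
            (X**2).sum(axis=1, keepdims=True)
            - 2.0 * X @ self.S_
            + (self.S_**2).sum(axis=0, keepdims=True)
        )
        order = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        out = np.zeros((X.shape[0], len(self.classes_)))
        for i in range(X.shape[0]):
            votes = self.y_[order[i]]
            for k, c in enumerate(self.classes_):
                out[i, k] = -np.sum(votes == c)
        return out


class LinearMarginClassifier(ClassifierMixin, BaseEstimator):
    """Linear max-margin (SVM) comparison baseline, delegated to sklearn."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        self._svc = SVC(kernel="linear", C=self.C).fit(X, y)
        self.classes_ = self._svc.classes_
        self.n_features_in_ = self._svc.n_features_in_
        return self

    def predict(self, X):
        check_is_fitted(self, "_svc")
        return self._svc.predict(X)


_REGISTRY = {
    "procrc": ProCRClassifier,
    "crc": CRClassifier,
    "src": SRClassifier,
    "knn": KNearestClassifier,
    "svm": LinearMarginClassifier,
}


def make_classifier(name: str, **params):
    """Instantiate a classifier by its short name."""
    try:
        cls = _REGISTRY[name.lower()]
    except KeyError:
        raise InputValidationError(
            f"unknown classifier {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
    return cls(**params)


# ---------------------------------------------------------------------------
# column-convention wrappers over the estimators
# ---------------------------------------------------------------------------

def fit_procrc(data: LabeledDataset, lam: float = 0.7, gamma: float = 0.001,
               normalize: bool = True) -> ProCRClassifier:
    """Fit ProCRC on a columns-as-samples dataset."""
    X, y = data.to_sklearn()
    return ProCRClassifier(lam=lam, gamma=gamma, normalize=normalize).fit(X, y)


def classify_procrc(model: ProCRClassifier, t: np.ndarray) -> ClassificationResult:
    return model.classify_one(t)


def fit_classify_crc(data: LabeledDataset, lam: float, t: np.ndarray,
                     normalize: bool = True) -> ClassificationResult:
    X, y = data.to_sklearn()
    return CRClassifier(lam=lam, normalize=normalize).fit(X, y).classify_one(t)


def fit_classify_src(data: LabeledDataset, lam: float, t: np.ndarray,
                     normalize: bool = True) -> ClassificationResult:
    X, y = data.to_sklearn()
    return SRClassifier(lam=lam, normalize=normalize).fit(X, y).classify_one(t)


def fit_classify_knn(data: LabeledDataset, k: int, t: np.ndarray) -> ClassificationResult:
    X, y = data.to_sklearn()
    return KNearestClassifier(k=k).fit(X, y).classify_one(t)
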