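import numpy as np
import pytest
from scipy.optimize import minimize

from nbds.classifiers import (
    CRClassifier,
    KNearestClassifier,
    ProCRClassifier,
    SRClassifier,
    classify_procrc,
    fit_classify_knn,
    fit_classify_src,
    fit_procrc,
)
from nbds.errors import InputValidationError
from nbds.types import LabeledDataset


def random_instance(rng, m=8, n=12, K=3):
    y = rng.integers(0, K, size=n)
    y[:K] = np.arange(K)  # every class non-empty
    S = rng.normal(size=(m, n))
    t = rng.normal(size=m)
    return S, y, t


def procrc_objective(A, S, y, t, lam, gamma):
    """The representation objective, written out directly as the oracle."""
    K = len(np.unique(y))
    SA = S @ A
    val = np.sum((t - SA) ** 2) + lam * np.sum(A**2)
    for c in np.unique(y):
        mask = y == c
        val += (gamma / K) * np.sum((SA - S[:, mask] @ A[mask]) ** 2)
    return val


def test_gamma_zero_reduces_to_ridge():
    rng = np.random.default_rng(0)
    for _ in range(5):
        S, y, t = random_instance(rng)
        lam = 0.3
        pro = ProCRClassifier(lam=lam, gamma=0.0, normalize=False).fit(S.T, y)
        A = pro.coefficients(t[None, :])[0]
        ridge = np.linalg.solve(S.T @ S + lam * np.eye(S.shape[1]), S.T @ t)
        assert np.max(np.abs(A - ridge)) < 1e-8
        # CRC's coefficient solve coincides with the gamma = 0 case
        crc = CRClassifier(lam=lam, normalize=False).fit(S.T, y)
        assert np.max(np.abs(crc.coefficients(t[None, :])[0] - ridge)) < 1e-8


def test_single_class_degenerates_to_ridge():
    rng = np.random.default_rng(1)
    S = rng.normal(size=(6, 8))
    y = np.zeros(8, dtype=int)
    t = rng.normal(size=6)
    pro = ProCRClassifier(lam=0.5, gamma=2.0, normalize=False).fit(S.T, y)
    ridge = np.linalg.solve(S.T @ S + 0.5 * np.eye(8), S.T @ t)
    assert np.max(np.abs(pro.coefficients(t[None, :])[0] - ridge)) < 1e-8


def test_closed_form_matches_numerical_minimizer():
    rng = np.random.default_rng(2)
    for _ in range(5):
        S, y, t = random_instance(rng)
        lam, gamma = 0.7, 0.001
        pro = ProCRClassifier(lam=lam, gamma=gamma, normalize=False).fit(S.T, y)
        A = pro.coefficients(t[None, :])[0]
        res = minimize(
            procrc_objective,
            np.zeros(S.shape[1]),
            args=(S, y, t, lam, gamma),
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 10000},
        )
        assert np.max(np.abs(A - res.x)) < 1e-5


def test_closed_form_is_a_minimum_under_perturbation():
    rng = np.random.default_rng(3)
    S, y, t = random_instance(rng)
    lam, gamma = 0.7, 0.001
    pro = ProCRClassifier(lam=lam, gamma=gamma, normalize=False).fit(S.T, y)
    A = pro.coefficients(t[None, :])[0]
    base = procrc_objective(A, S, y, t, lam, gamma)
    for _ in range(1000):
        eps = rng.normal(scale=1e-3, size=A.shape)
        assert procrc_objective(A + eps, S, y, t, lam, gamma) >= base


def test_training_column_classified_to_its_class():
    rng = np.random.default_rng(4)
    # well-separated classes: three orthogonal-ish clusters
    centers = np.eye(3) * 5
    cols, y = [], []
    for k in range(3):
        for _ in range(4):
            cols.append(centers[k] + rng.normal(scale=0.1, size=3))
            y.append(k)
    S = np.array(cols).T
    data = LabeledDataset(S, np.array(y))
    model = fit_procrc(data, lam=1e-6, gamma=0.001)
    for j in (0, 5, 10):
        result = classify_procrc(model, S[:, j])
        assert result.label == y[j]
        assert result.label == data.classes[np.argmin(result.residuals)]


def test_huge_lambda_shrinks_solution_and_exact_ties_break_low():
    rng = np.random.default_rng(5)
    S, y, t = random_instance(rng)
    pro = ProCRClassifier(lam=1e9, gamma=0.001, normalize=False).fit(S.T, y)
    result = pro.classify_one(t)
    assert np.max(np.abs(result.coefficients)) < 1e-8
    assert np.all(result.residuals < 1e-6)
    # an exact residual tie (t = 0 gives A = 0, all residuals exactly 0)
    # resolves to the lowest class index
    tied = pro.classify_one(np.zeros_like(t))
    assert np.all(tied.residuals == 0.0)
    assert tied.label == pro.classes_[0]


def test_mirrored_two_class_dataset():
    rng = np.random.default_rng(6)
    S1 = rng.normal(size=(6, 4))
    S = np.hstack([S1, -S1])
    y = np.array([0] * 4 + [1] * 4)
    t = S1 @ np.array([0.5, 0.3, 0.1, 0.1])  # in class-0 span
    pro = ProCRClassifier(lam=1e-4, gamma=0.001, normalize=False).fit(S.T, y)
    result = pro.classify_one(t)
    assert result.residuals[0] < result.residuals[1]
    assert result.label == 0


def test_scaling_test_vector_scales_residuals_not_label():
    rng = np.random.default_rng(7)
    S, y, t = random_instance(rng)
    pro = ProCRClassifier(lam=0.7, gamma=0.001, normalize=False).fit(S.T, y)
    r1 = pro.classify_one(t)
    r2 = pro.classify_one(3.0 * t)
    assert np.allclose(r2.residuals, 3.0 * r1.residuals, rtol=1e-9)
    assert np.allclose(r2.coefficients, 3.0 * r1.coefficients, rtol=1e-9)
    assert r1.label == r2.label


def test_crc_orthonormal_single_sample_classes():
    S = np.eye(4)  # four orthonormal one-sample classes
    y = np.arange(4)
    crc = CRClassifier(lam=1e-6, normalize=False).fit(S.T, y)
    for k in range(4):
        assert crc.classify_one(S[:, k]).label == k


def test_crc_lambda_infinity_kills_coefficients():
    rng = np.random.default_rng(8)
    S, y, t = random_instance(rng)
    crc = CRClassifier(lam=1e12, normalize=False).fit(S.T, y)
    assert np.max(np.abs(crc.coefficients(t[None, :]))) < 1e-9


def test_crc_matches_numerical_minimizer():
    rng = np.random.default_rng(9)
    for _ in range(5):
        S, y, t = random_instance(rng)
        lam = 0.01
        crc = CRClassifier(lam=lam, normalize=False).fit(S.T, y)
        A = crc.coefficients(t[None, :])[0]

        def obj(a):
            return np.sum((t - S @ a) ** 2) + lam * np.sum(a**2)

        def grad(a):
            return 2 * S.T @ (S @ a - t) + 2 * lam * a

        res = minimize(obj, np.zeros(S.shape[1]), jac=grad, method="BFGS",
                       options={"gtol": 1e-12})
        assert np.max(np.abs(A - res.x)) < 1e-6


def src_oracle(S, t, lam):
    """Convex-programming oracle: split A = p - q with p, q >= 0 so the
    l1 term becomes linear, then solve the smooth bounded problem."""
    n = S.shape[1]

    def obj(z):
        a = z[:n] - z[n:]
        return np.sum((t - S @ a) ** 2) + lam * np.sum(z)

    def grad(z):
        a = z[:n] - z[n:]
        g = 2 * S.T @ (S @ a - t)
        return np.concatenate([g, -g]) + lam

    res = minimize(obj, np.zeros(2 * n), jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * n),
                   options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 20000})
    return res.x[:n] - res.x[n:], res.fun


def test_src_large_lambda_zeroes_all_coefficients():
    rng = np.random.default_rng(10)
    S, y, t = random_instance(rng)
    lam = 10.0 * np.max(np.abs(2 * S.T @ t))
    src = SRClassifier(lam=lam, normalize=False).fit(S.T, y)
    assert np.array_equal(src.coefficients(t[None, :])[0], np.zeros(S.shape[1]))


def test_src_concentrates_on_matching_training_column():
    rng = np.random.default_rng(11)
    S, y, _ = random_instance(rng, m=10, n=9, K=3)
    S = S / np.linalg.norm(S, axis=0)
    j = 4
    t = S[:, j]
    src = SRClassifier(lam=1e-4, normalize=False).fit(S.T, y)
    A = src.coefficients(t[None, :])[0]
    assert np.argmax(np.abs(A)) == j
    assert src.classify_one(t).label == y[j]


def test_src_objective_matches_convex_oracle():
    rng = np.random.default_rng(12)
    for _ in range(5):
        S, y, t = random_instance(rng)
        lam = 0.1
        src = SRClassifier(lam=lam, normalize=False, tol=1e-10).fit(S.T, y)
        A = src.coefficients(t[None, :])[0]
        obj = np.sum((t - S @ A) ** 2) + lam * np.sum(np.abs(A))
        _, opt = src_oracle(S, t, lam)
        assert obj <= opt + 1e-5


def test_knn_matches_exhaustive_sort():
    rng = np.random.default_rng(13)
    S, y, _ = random_instance(rng, m=5, n=14, K=3)
    T = rng.normal(size=(6, 5))
    knn = KNearestClassifier(k=3).fit(S.T, y)
    preds = knn.predict(T)
    for t, pred in zip(T, preds):
        d = np.linalg.norm(S - t[:, None], axis=0)
        nearest = y[np.argsort(d, kind="stable")[:3]]
        classes, counts = np.unique(nearest, return_counts=True)
        assert pred == classes[np.argmax(counts)]


def test_knn_k1_returns_exact_match_and_full_tie_breaks_low():
    S = np.array([[0.0, 1.0, 2.0, 3.0]])
    y = np.array([1, 1, 2, 2])
    data = LabeledDataset(S, y)
    assert fit_classify_knn(data, 1, np.array([1.01])).label == 1
    # k = n on a balanced set: tie resolves to the lowest class index
    assert fit_classify_knn(data, 4, np.array([1.5])).label == 1


def test_dimension_mismatch_rejected():
    rng = np.random.default_rng(14)
    S, y, _ = random_instance(rng)
    pro = ProCRClassifier().fit(S.T, y)
    with pytest.raises(InputValidationError):
        pro.predict(np.zeros((1, S.shape[0] + 1)))


def test_wrappers_follow_column_convention():
    rng = np.random.default_rng(15)
    S, y, t = random_instance(rng)
    data = LabeledDataset(S, y)
    result = fit_classify_src(data, 0.1, t)
    assert result.label in data.classes
    assert result.residuals.shape == (len(data.classes),)


def test_classifiers_are_deterministic():
    rng = np.random.default_rng(16)
    S, y, _ = random_instance(rng, m=6, n=12, K=2)
    T = rng.normal(size=(8, 6))
    for clf in (
        ProCRClassifier(),
        CRClassifier(),
        SRClassifier(),
        KNearestClassifier(k=3),
    ):
        a = clf.fit(S.T, y).predict(T)
        b = clf.fit(S.T.copy(), y.copy()).predict(T.copy())
        assert np.array_equal(a, b)
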