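"""Low-overhead support-vector fits for permutation and searchlight hot loops.

Both classification (C-SVC, linear kernel via precomputed Gram) and
regression (nu-SVR) are solved by libsvm, the same solver that backs
sklearn.svm.SVC / NuSVR.  The public sklearn estimators spend most of
their per-call time in input validation, which dominates when the fits
are tiny (a handful of samples) but number in the millions, as they do
in permutation nulls and whole-brain searchlights.  We therefore call
scikit-learn's bundled libsvm binding directly and fall back to the
public estimators if the private binding is unavailable.  Agreement of
the two routes is asserted in the test suite.

The batched searchlight path does not call libsvm at all: it solves the
dual SVM problem for thousands of spheres simultaneously with a
vectorised SMO loop (`batch_svc_accuracy`), which is exact for these
tiny problems and is tested voxel-by-voxel against sklearn's SVC.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_RAW = True
except Exception:  # pragma: no cover
    _libsvm = None
    _HAVE_RAW = False

_EMPTY = np.empty(0)


# ---------------------------------------------------------------------------
# C-SVC on a precomputed (linear) Gram matrix
# ---------------------------------------------------------------------------

def svc_train_predict(gram_train: np.ndarray, y_train: np.ndarray,
                      gram_test: np.ndarray, cost: float = 1.0) -> np.ndarray:
    """Train a C-SVC on a precomputed kernel and label the test rows.

    ``gram_train`` is (n_train, n_train), ``gram_test`` is
    (n_test, n_train); ``y_train`` holds binary labels (any dtype).
    Returns predicted labels with the same dtype as ``y_train``.
    """
    classes, y_enc = np.unique(y_train, return_inverse=True)
    if classes.size != 2:
        raise ValueError("svc_train_predict requires exactly two classes")
    if _HAVE_RAW:
        yf = np.ascontiguousarray(y_enc, dtype=np.float64)
        out = _libsvm.fit(np.ascontiguousarray(gram_train, dtype=np.float64), yf,
                          svm_type=0, kernel="precomputed", C=float(cost),
                          class_weight=_EMPTY, sample_weight=_EMPTY)
        support, sv, n_class_sv, sv_coef, intercept, prob_a, prob_b = out[:7]
        pred = _libsvm.predict(np.ascontiguousarray(gram_test, dtype=np.float64),
                               support, sv, n_class_sv, sv_coef, intercept,
                               prob_a, prob_b, svm_type=0, kernel="precomputed",
                               class_weight=_EMPTY, sample_weight=_EMPTY)
        return classes[pred.astype(int)]
    from sklearn.svm import SVC  # pragma: no cover - fallback route

    model = SVC(kernel="precomputed", C=float(cost))
    model.fit(gram_train, y_enc)
    return classes[model.predict(gram_test).astype(int)]


# ---------------------------------------------------------------------------
# nu-SVR on a precomputed (linear) Gram matrix
# ---------------------------------------------------------------------------

def nusvr_train_predict(gram_train: np.ndarray, y_train: np.ndarray,
                        gram_test: np.ndarray, nu: float = 0.5,
                        cost: float = 1.0) -> np.ndarray:
    """Train a linear nu-SVR on a precomputed kernel; predict test rows."""
    if _HAVE_RAW:
        out = _libsvm.fit(np.ascontiguousarray(gram_train, dtype=np.float64),
                          np.ascontiguousarray(y_train, dtype=np.float64),
                          svm_type=4, kernel="precomputed", C=float(cost),
                          nu=float(nu), class_weight=_EMPTY, sample_weight=_EMPTY)
        support, _, _, sv_coef, intercept = out[:5]
        # linear/precomputed: f(x) = sum_i coef_i K(x, sv_i) + b
        return np.asarray(gram_test)[:, support] @ sv_coef.ravel() + intercept[0]
    from sklearn.svm import NuSVR  # pragma: no cover - fallback route

    model = NuSVR(kernel="precomputed", nu=float(nu), C=float(cost))
    model.fit(gram_train, y_train)
    return model.predict(gram_test)


# ---------------------------------------------------------------------------
# Batched linear SVM over many searchlight spheres at once
# ---------------------------------------------------------------------------

def _batch_smo(K: np.ndarray, y: np.ndarray, cost: float,
               tol: float = 1e-5, max_sweeps: int = 200):
    """Solve min 1/2 a'Qa - e'a, 0<=a<=C, y'a=0 for V problems at once.

    ``K`` is an (n, n, V) Gram stack sharing labels ``y`` in {-1,+1}
    (voxels last so each K[i, j] is a contiguous vector).  Returns
    (alpha (n,V), f (n,V)) with f_i = sum_j a_j y_j K_ij.  Plain
    pairwise SMO; for the tiny n of searchlight folds it converges in a
    handful of sweeps.
    """
    n = K.shape[0]
    V = K.shape[2]
    C = float(cost)
    alpha = np.zeros((n, V))
    f = np.zeros((n, V))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    inv_eta = []
    for i, j in pairs:
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        inv_eta.append(np.where(eta > 1e-12, 1.0 / np.maximum(eta, 1e-12), 0.0))
    for _ in range(max_sweeps):
        max_delta = 0.0
        for (i, j), ie in zip(pairs, inv_eta):
            s = y[i] * y[j]
            aj = alpha[j] + y[j] * ((f[i] - y[i]) - (f[j] - y[j])) * ie
            if s > 0:
                gamma = alpha[i] + alpha[j]
                np.clip(aj, np.maximum(0.0, gamma - C), np.minimum(C, gamma), out=aj)
            else:
                diff = alpha[j] - alpha[i]
                np.clip(aj, np.maximum(0.0, diff), np.minimum(C, C + diff), out=aj)
            d_j = aj - alpha[j]
            step = float(np.max(np.abs(d_j)))
            if step <= 0.0:
                continue
            alpha[j] = aj
            alpha[i] -= s * d_j
            u = d_j * y[j]
            for k in range(n):
                f[k] += u * (K[k, j] - K[k, i])
            max_delta = max(max_delta, step)
        if max_delta < tol:
            break
    return alpha, f


def _batch_bias(alpha: np.ndarray, f: np.ndarray, y: np.ndarray, cost: float):
    """libsvm-style rho: average over free SVs, else midpoint of KKT bounds."""
    C = float(cost)
    eps = 1e-9 * max(C, 1.0)
    free = (alpha > eps) & (alpha < C - eps)
    resid = y[:, None] - f  # candidate bias per point
    n_free = free.sum(axis=0)
    b_free = np.where(free, resid, 0.0).sum(axis=0) / np.maximum(n_free, 1)
    # b is bounded above by points with (y=+1, alpha=C) or (y=-1, alpha=0)
    # and below by (y=+1, alpha=0) or (y=-1, alpha=C); free SVs pin it.
    up_mask = np.where(y[:, None] > 0, alpha > eps, alpha < C - eps)
    lo_mask = np.where(y[:, None] > 0, alpha < C - eps, alpha > eps)
    ub = np.where(up_mask, resid, np.inf).min(axis=0)
    lb = np.where(lo_mask, resid, -np.inf).max(axis=0)
    b_bound = 0.5 * (np.where(np.isfinite(ub), ub, lb) +
                     np.where(np.isfinite(lb), lb, ub))
    return np.where(n_free > 0, b_free, b_bound)


def batch_svc_decision(K_train: np.ndarray, y_train: np.ndarray,
                       K_cross: np.ndarray, cost: float = 1.0) -> np.ndarray:
    """Decision values of batched linear SVCs on held-out samples.

    ``K_train``: (n_tr, n_tr, V) Gram stacks; ``y_train``: (n_tr,) in
    {-1, +1}; ``K_cross``: (n_te, n_tr, V) test-vs-train Gram rows.
    Returns (n_te, V) decision values; positive means class +1.
    """
    alpha, f = _batch_smo(K_train, y_train, cost)
    b = _batch_bias(alpha, f, y_train, cost)
    coef = alpha * y_train[:, None]  # (n_tr, V)
    return np.einsum("tiv,iv->tv", K_cross, coef) + b[None, :]
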