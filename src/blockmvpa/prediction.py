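"""Predicting individual-difference scores from ROI contrast patterns.

A linear nu-SVR (cost 1, nu 0.5) maps each participant's why-how
contrast pattern inside an ROI to their behavioral score (z-scored
within sample).  Accuracy is the Pearson correlation between
predicted and observed scores under leave-one-participant-out
cross-validation; the cross-sample variant trains one model on pooled
neurotypical samples (features and labels z-scored per sample) and
tests on a held-out group.  Univariate controls correlate the ROI-mean
contrast, or per-subject decoding accuracies, with the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._fastsvm import nusvr_train_predict


def zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=axis, keepdims=True)
    return (x - x.mean(axis=axis, keepdims=True)) / np.where(sd > 0, sd, 1.0)


@dataclass
class PredictionResult:
    """Observed vs predicted scores with the derived accuracy statistics."""

    predicted: np.ndarray
    observed: np.ndarray
    r: float
    r2: float
    p: float | None = None
    null_q5: float | None = None
    null_q95: float | None = None
    scheme: str = "lopo"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.predicted) != len(self.observed):
            raise ValueError("predicted and observed lengths differ")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation outside [-1, 1]")


def prediction_accuracy(predicted, observed) -> tuple[float, float]:
    """Pearson r of predicted vs observed scores, and R^2 = r^2."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if predicted.std() == 0 or observed.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(predicted, observed)[0, 1])
    return r, r * r


class PatternSVR(BaseEstimator, RegressorMixin):
    """Linear nu-SVR over multivoxel contrast patterns (libsvm backend).

    Parameters
    ----------
    nu : float, default 0.5
        Upper bound on the fraction of margin errors / lower bound on
        the fraction of support vectors.
    cost : float, default 1.0
        The fixed SVM cost parameter c.
    """

    def __init__(self, nu: float = 0.5, cost: float = 1.0):
        self.nu = nu
        self.cost = cost

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("features and labels must be finite")
        if y.std() == 0:
            raise ValueError("labels are constant")
        self.X_train_ = X
        self.y_train_ = y
        self.gram_ = X @ X.T
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return nusvr_train_predict(self.gram_, self.y_train_, X @ self.X_train_.T,
                                   nu=self.nu, cost=self.cost)


def lopo_svr(features: np.ndarray, labels: np.ndarray, nu: float = 0.5,
             cost: float = 1.0, gram: np.ndarray | None = None) -> PredictionResult:
    """Leave-one-participant-out nu-SVR prediction of scores.

    ``features`` is (n_subjects, n_voxels); ``labels`` the z-scored
    scores.  Each of the n folds trains on n-1 subjects and predicts
    the held-out one; accuracy is the Pearson r of predictions vs
    observations across subjects.  ``gram`` may carry the precomputed
    linear kernel (labels permute, the kernel does not).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("features must be (n_subjects, n_voxels)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if y.std() == 0:
        raise ValueError("labels are constant; correlation undefined")
    if gram is None:
        gram = X @ X.T
    pred = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx[idx != i]
        pred[i] = nusvr_train_predict(gram[np.ix_(tr, tr)], y[tr],
                                      gram[np.ix_([i], tr)], nu=nu, cost=cost)[0]
    r, r2 = prediction_accuracy(pred, y)
    return PredictionResult(predicted=pred, observed=y, r=r, r2=r2, scheme="lopo")


def cross_sample_svr(train_samples, test_features, test_labels,
                     nu: float = 0.5, cost: float = 1.0,
                     standardize: bool = True) -> PredictionResult:
    """Train on pooled samples, test on a held-out group.

    ``train_samples`` is a sequence of (features, labels) pairs, one
    per participant sample; features (each voxel across subjects) and
    labels are z-scored within each sample independently -- including
    the test sample -- before pooling, to absorb scanner and
    instrument differences.
    """
    if len(train_samples) < 2:
        raise ValueError("need at least 2 training samples")
    n_vox = {np.asarray(f).shape[1] for f, _ in train_samples}
    n_vox.add(np.asarray(test_features).shape[1])
    if len(n_vox) != 1:
        raise ValueError("voxel lists differ across samples")
    Xs, ys = [], []
    for f, s in train_samples:
        f = np.asarray(f, dtype=float)
        s = np.asarray(s, dtype=float)
        Xs.append(zscore(f) if standardize else f)
        ys.append(zscore(s) if standardize else s)
    X_train = np.vstack(Xs)
    y_train = np.concatenate(ys)
    X_test = np.asarray(test_features, dtype=float)
    y_test = np.asarray(test_labels, dtype=float)
    if standardize:
        X_test = zscore(X_test)
        y_test = zscore(y_test)
    model = PatternSVR(nu=nu, cost=cost).fit(X_train, y_train)
    pred = model.predict(X_test)
    r, r2 = prediction_accuracy(pred, y_test)
    return PredictionResult(predicted=pred, observed=y_test, r=r, r2=r2,
                            scheme="cross_sample",
                            extras={"n_train": len(y_train)})


def roi_mean_univariate_assoc(contrast_values: np.ndarray, roi: np.ndarray,
                              scores: np.ndarray) -> tuple[float, float]:
    """Correlate each subject's ROI-mean contrast with the scores.

    ``contrast_values`` is (n_subjects, n_voxels) over the full grid or
    an ROI extraction; ``roi`` a boolean voxel selector in the same
    space.  Returns (Pearson r, two-tailed p).
    """
    roi = np.asarray(roi).reshape(-1).astype(bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = np.asarray(contrast_values, dtype=float)
    means = vals.reshape(vals.shape[0], -1)[:, roi].mean(axis=1)
    scores = np.asarray(scores, dtype=float)
    if means.size < 3:
        raise ValueError("need at least 3 subjects")
    if means.std() == 0 or scores.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(means, scores)
    return float(r), float(p)


def accuracy_score_correlation(accuracies: np.ndarray,
                               scores: np.ndarray) -> tuple[float, float]:
    """Correlate per-subject ROI decoding accuracies with scores."""
    acc = np.asarray(accuracies, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if acc.size < 3 or acc.shape != scores.shape:
        raise ValueError("need matched vectors of length >= 3")
    if acc.std() == 0 or scores.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(acc, scores)
    return float(r), float(p)
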