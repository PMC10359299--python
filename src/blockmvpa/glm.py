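"""Block-wise GLM estimation of BOLD responses.

Each task block gets its own boxcar regressor (first target onset to
final image offset) convolved with the canonical double-gamma HRF.
Low-frequency drifts are absorbed by a cosine (DCT) basis up to a
1/100 Hz cutoff, head motion and spike frames enter as nuisance
columns, and coefficients are estimated either by OLS or by a robust
weighted least-squares scheme that downweights high-variance
timepoints.  The per-block coefficient patterns are the inputs to all
multivariate decoding; the social contrast (mean of why-face and
why-hand block betas minus mean of how-face and how-hand block betas)
feeds the individual-difference prediction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .design import BlockDesign


# ---------------------------------------------------------------------------
# Hemodynamic response function
# ---------------------------------------------------------------------------

def canonical_hrf(t, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_dispersion: float = 1.0, undershoot_dispersion: float = 1.0,
                  undershoot_ratio: float = 1.0 / 6.0):
    """Canonical double-gamma HRF, normalised to unit peak.

    The response is a gamma density peaking ~5 s after onset minus a
    scaled, later gamma density modelling the post-stimulus undershoot.
    ``peak_delay``/``undershoot_delay`` are the gamma means in seconds
    (conventional values 6 and 16), dispersions their scales, and
    ``undershoot_ratio`` the undershoot amplitude relative to the peak.
    """
    if peak_delay <= 0 or undershoot_delay <= 0 or peak_dispersion <= 0 \
            or undershoot_dispersion <= 0:
        raise ValueError("HRF shape parameters must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")

    def _raw(tt):
        peak = stats.gamma.pdf(tt, peak_delay / peak_dispersion, scale=peak_dispersion)
        under = stats.gamma.pdf(tt, undershoot_delay / undershoot_dispersion,
                                scale=undershoot_dispersion)
        return peak - undershoot_ratio * under

    grid = np.arange(0.0, 32.0, 0.1)
    scale = _raw(grid).max()
    return _raw(t) / scale


def hrf_kernel(dt: float, duration: float = 32.0, **hrf_params) -> np.ndarray:
    """HRF sampled every ``dt`` seconds on [0, duration)."""
    return canonical_hrf(np.arange(0.0, duration, dt), **hrf_params)


def block_regressors(design: BlockDesign, oversample: int = 10,
                     **hrf_params) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved boxcar regressor per block, sampled at the TR.

    Boxcars span [block onset, final image offset), are convolved with
    the HRF on a grid ``oversample`` times finer than the TR, and then
    sampled at volume acquisition times (t = k * tr).
    """
    tr = design.tr
    dt = tr / oversample
    n_fine = design.n_volumes * oversample
    t_fine = np.arange(n_fine) * dt
    h = hrf_kernel(dt, **hrf_params)
    scan_end = design.n_volumes * tr
    cols, names = [], []
    for bi, b in enumerate(design.blocks):
        if b.onset < 0 or b.offset > scan_end:
            raise ValueError(f"block {bi} lies outside the scan")
        box = ((t_fine >= b.onset) & (t_fine < b.offset)).astype(float)
        conv = np.convolve(box, h)[:n_fine] * dt
        cols.append(conv[::oversample])
        names.append(f"{b.inference}_{b.target}_block{bi:02d}")
    return np.column_stack(cols), names


def dct_drift_basis(n_volumes: int, tr: float, cutoff: float = 100.0) -> np.ndarray:
    """Cosine drift basis spanning periods longer than ``cutoff`` seconds."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    order = int(np.floor(2.0 * n_volumes * tr / cutoff))
    t = np.arange(n_volumes)
    basis = [np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
             for k in range(1, order + 1)]
    return np.column_stack(basis) if basis else np.empty((n_volumes, 0))


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    names: list[str]
    tr: float

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")
        task = self.task_columns
        if task and not np.all(np.ptp(self.matrix[:, task], axis=0) > 0):
            raise ValueError("all-zero task column")

    @property
    def task_columns(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if re.search(r"_block\d+$", n)]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def build_design_matrix(design: BlockDesign,
                        highpass_cutoff: float = 100.0,
                        motion: np.ndarray | None = None,
                        spike_frames=(),
                        oversample: int = 10,
                        hrf_params: dict | None = None) -> DesignMatrix:
    """Assemble task, motion, spike, drift and intercept columns."""
    X_task, names = block_regressors(design, oversample=oversample,
                                     **(hrf_params or {}))
    cols = [X_task]
    n = design.n_volumes
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n, 6):
            raise ValueError(f"motion must be ({n}, 6), got {motion.shape}")
        cols.append(motion - motion.mean(axis=0))
        names += [f"motion{k}" for k in range(1, 7)]
    for fr in sorted(set(int(f) for f in spike_frames)):
        if not 0 <= fr < n:
            raise ValueError(f"spike frame {fr} outside scan")
        col = np.zeros(n)
        col[fr] = 1.0
        cols.append(col[:, None])
        names.append(f"spike{fr:04d}")
    drift = dct_drift_basis(n, design.tr, highpass_cutoff)
    if drift.shape[1]:
        cols.append(drift)
        names += [f"drift{k}" for k in range(1, drift.shape[1] + 1)]
    cols.append(np.ones((n, 1)))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=names, tr=design.tr)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

class RobustWLS(BaseEstimator, RegressorMixin):
    """Multi-output linear regression with robust timepoint weighting.

    Ordinary least squares assumes homoscedastic noise over time;
    scanner spikes and residual motion violate that.  This estimator
    iteratively reweights timepoints by the inverse of their residual
    variance, with the variance of each timepoint pooled across all
    output columns (voxels), then solves the weighted least-squares
    problem.  With ``robust=False`` it reduces to OLS.

    Parameters
    ----------
    robust : bool, default True
    n_iter : int, default 2
        Reweighting iterations.
    tol : float, default 1e-6
        Stop early when the maximum weight change falls below this.

    Attributes
    ----------
    coef_ : ndarray of shape (n_outputs, n_features)
    weights_ : ndarray of shape (n_samples,)
        Final normalised timepoint weights (all ones under OLS).
    sigma2_ : ndarray of shape (n_samples,)
        Estimated per-timepoint noise variance (robust mode only).
    """

    def __init__(self, robust: bool = True, n_iter: int = 2, tol: float = 1e-6):
        self.robust = robust
        self.n_iter = n_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if n <= p:
            raise ValueError("need more timepoints than regressors")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # identify (nearly) collinear columns from the R diagonal
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = [i for i in range(p) if diag[i] < 1e-8 * diag.max()]
            raise ValueError(f"design matrix is rank deficient (rank {rank} < {p}); "
                             f"suspect columns {bad}")
        def _solve(Xw, Yw):
            # normal equations with Cholesky; X was checked full rank above
            return linalg.cho_solve(linalg.cho_factor(Xw.T @ Xw), Xw.T @ Yw)

        def _leverage(Xw):
            return np.einsum("ij,ij->i", Xw @ np.linalg.inv(Xw.T @ Xw), Xw)

        w = np.ones(n)
        beta = _solve(X, Y)
        if self.robust:
            for _ in range(self.n_iter):
                resid = Y - X @ beta
                # E[r_t^2] = (1 - h_tt) sigma_t^2: divide out the leverage so
                # homoscedastic data yield (asymptotically) equal weights
                h = _leverage(X * np.sqrt(w)[:, None])
                sigma2 = np.mean(resid ** 2, axis=1) / np.clip(1.0 - h, 1e-6, None)
                sigma2 = np.maximum(sigma2, 1e-12 * sigma2.max() + 1e-300)
                w_new = 1.0 / sigma2
                w_new *= n / w_new.sum()
                if np.max(np.abs(w_new - w)) < self.tol:
                    w = w_new
                    break
                w = w_new
                sw = np.sqrt(w)[:, None]
                beta = _solve(X * sw, Y * sw)
            self.sigma2_ = sigma2
        self.weights_ = w
        self.coef_ = beta.T
        self.n_features_in_ = p
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_.T


@dataclass
class BetaResult:
    """Per-block coefficient patterns for one subject."""

    betas: np.ndarray  # (n_regressors, n_voxels)
    names: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None

    def block_betas(self) -> tuple[np.ndarray, list[str]]:
        idx = [i for i, n in enumerate(self.names) if re.search(r"_block\d+$", n)]
        return self.betas[idx], [self.names[i] for i in idx]


def fit_glm(series: np.ndarray, X: DesignMatrix, robust: bool = True,
            n_iter: int = 2, tol: float = 1e-6) -> BetaResult:
    """Fit the block GLM to a (n_volumes, n_voxels) data matrix."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] != X.n_volumes:
        raise ValueError("series must be (n_volumes, n_voxels)")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    est = RobustWLS(robust=robust, n_iter=n_iter, tol=tol).fit(X.matrix, series)
    return BetaResult(betas=est.coef_.T, names=list(X.names), weights=est.weights_)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def _block_name_parts(name: str):
    m = re.match(r"(why|how)_(faces|hands|nonsocial)_block(\d+)$", name)
    return m.groups()[:2] if m else None


def contrast_weights(names: list[str], positive, negative) -> np.ndarray:
    """Mean-of-positive minus mean-of-negative weights over block columns.

    ``positive`` / ``negative`` are collections of (inference, target)
    pairs.  Raises if any requested condition has no block column.
    """
    pos_idx = {c: [] for c in positive}
    neg_idx = {c: [] for c in negative}
    for i, n in enumerate(names):
        parts = _block_name_parts(n)
        if parts in pos_idx:
            pos_idx[parts].append(i)
        elif parts in neg_idx:
            neg_idx[parts].append(i)
    for cond, idx in {**pos_idx, **neg_idx}.items():
        if not idx:
            raise ValueError(f"condition {cond} not present in this design")
    w = np.zeros(len(names))
    pos_all = [i for idx in pos_idx.values() for i in idx]
    neg_all = [i for idx in neg_idx.values() for i in idx]
    w[pos_all] = 1.0 / len(pos_all)
    w[neg_all] = -1.0 / len(neg_all)
    return w


def social_contrast_weights(names: list[str]) -> np.ndarray:
    """why - how over the social (faces, hands) blocks."""
    return contrast_weights(names,
                            positive=[("why", "faces"), ("why", "hands")],
                            negative=[("how", "faces"), ("how", "hands")])


def nonsocial_contrast_weights(names: list[str]) -> np.ndarray:
    """why - how over the nonsocial blocks."""
    return contrast_weights(names, positive=[("why", "nonsocial")],
                            negative=[("how", "nonsocial")])


def contrast_image(result: BetaResult, weights: np.ndarray) -> np.ndarray:
    """Voxel-wise weighted sum of beta patterns."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (result.betas.shape[0],):
        raise ValueError("one weight per regressor required")
    return weights @ result.betas
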