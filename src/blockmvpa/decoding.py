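"""Decoding social vs factual inference from block-wise beta patterns.

A linear support-vector machine (cost 1) classifies why vs how blocks
from multivoxel patterns, cross-validated by holding out one why and
one how block per fold (all ordered pairs).  The searchlight variant
runs the same classifier on a sphere (radius 4 voxels) around every
in-mask voxel and writes the accuracy to the sphere's centre; group
ROI discovery tests the resulting accuracy maps against the 50%
chance level with a max-statistic sign-flip permutation and keeps
6-connected clusters of at least 5 voxels, intersected across target
conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from sklearn.base import BaseEstimator, ClassifierMixin

from ._fastsvm import batch_svc_decision, svc_train_predict
from .glm import BetaResult

CHANCE_PCT = 50.0


# ---------------------------------------------------------------------------
# Pattern container
# ---------------------------------------------------------------------------

@dataclass
class BetaPatternSet:
    """Labelled block-wise pattern vectors for one subject."""

    patterns: np.ndarray  # (n_blocks, n_voxels)
    inference: np.ndarray  # 'why' / 'how' per block
    target: np.ndarray  # 'faces' / 'hands' / 'nonsocial' per block
    block_ids: np.ndarray | None = None
    voxel_index: np.ndarray | None = None  # flat voxel ids defining column order

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.inference = np.asarray(self.inference)
        self.target = np.asarray(self.target)
        n = self.patterns.shape[0]
        if self.inference.shape != (n,) or self.target.shape != (n,):
            raise ValueError("one label pair per block required")
        if self.block_ids is None:
            self.block_ids = np.arange(n)
        if np.unique(self.block_ids).size != n:
            raise ValueError("duplicate block ids")
        for cls in ("why", "how"):
            if (self.inference == cls).sum() < 1:
                raise ValueError(f"no {cls!r} blocks present")

    @classmethod
    def from_betas(cls, result: BetaResult, voxel_index=None) -> "BetaPatternSet":
        block_b, names = result.block_betas()
        inference = np.array([n.split("_")[0] for n in names])
        target = np.array([n.split("_")[1] for n in names])
        pat = block_b if voxel_index is None else block_b[:, voxel_index]
        return cls(patterns=pat, inference=inference, target=target,
                   voxel_index=None if voxel_index is None else np.asarray(voxel_index))

    def select_target(self, target: str) -> "BetaPatternSet":
        keep = self.target == target
        return BetaPatternSet(patterns=self.patterns[keep], inference=self.inference[keep],
                              target=self.target[keep], block_ids=self.block_ids[keep],
                              voxel_index=self.voxel_index)


# ---------------------------------------------------------------------------
# Searchlight geometry and cross-validation folds
# ---------------------------------------------------------------------------

def sphere_offsets(radius: int = 4) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius, lexicographic order."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = x ** 2 + y ** 2 + z ** 2 <= radius ** 2
    return np.column_stack([x[keep], y[keep], z[keep]])


def leave_two_blocks_out_folds(inference_labels) -> list[tuple[np.ndarray, np.ndarray]]:
    """All (why, how) held-out pairs; train on the remaining blocks."""
    labels = np.asarray(inference_labels)
    why = np.flatnonzero(labels == "why")
    how = np.flatnonzero(labels == "how")
    if why.size < 2 or how.size < 2:
        raise ValueError("need at least 2 blocks per inference class for CV")
    all_idx = np.arange(labels.size)
    folds = []
    for w in why:
        for h in how:
            test = np.array([w, h])
            folds.append((np.setdiff1d(all_idx, test), test))
    return folds


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

class PatternDecoder(BaseEstimator, ClassifierMixin):
    """Linear SVM (libsvm, fixed cost) over multivoxel patterns.

    A thin sklearn-style estimator: ``fit(X, y)`` trains on labelled
    block patterns, ``predict(X)`` labels new ones.  Internally the
    linear kernel is precomputed so that repeated fits during
    cross-validation and permutation reuse the Gram matrix.
    """

    def __init__(self, cost: float = 1.0):
        self.cost = cost

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary classification only")
        self.X_train_ = X
        self.y_train_ = y
        self.gram_ = X @ X.T
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return svc_train_predict(self.gram_, self.y_train_, X @ self.X_train_.T,
                                 cost=self.cost)


def decode_patterns(patterns, inference_labels, folds=None, cost: float = 1.0,
                    gram: np.ndarray | None = None) -> float:
    """Cross-validated why-vs-how decoding accuracy in percent.

    ``folds`` defaults to all leave-two-blocks-out (why, how) pairs.
    A precomputed linear Gram matrix may be passed to speed up
    permutation loops (the labels change, the kernel does not).
    """
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(inference_labels)
    if folds is None:
        folds = leave_two_blocks_out_folds(y)
    if gram is None:
        gram = X @ X.T
    if np.ptp(X, axis=0).max() == 0:
        warnings.warn("all training patterns identical across blocks; "
                      "decoding is degenerate")
    n_correct = 0
    n_total = 0
    for train, test in folds:
        if np.unique(y[train]).size < 2:
            raise ValueError("a fold has fewer than one training pattern per class")
        pred = svc_train_predict(gram[np.ix_(train, train)], y[train],
                                 gram[np.ix_(test, train)], cost=cost)
        n_correct += int((pred == y[test]).sum())
        n_total += test.size
    return 100.0 * n_correct / n_total


def roi_decode(pattern_set: BetaPatternSet, cost: float = 1.0) -> float:
    """Leave-two-blocks-out decoding accuracy on an ROI pattern set."""
    return decode_patterns(pattern_set.patterns, pattern_set.inference, cost=cost)


# ---------------------------------------------------------------------------
# Searchlight
# ---------------------------------------------------------------------------

def _sphere_gram_stack(betas4d: np.ndarray, mask: np.ndarray,
                       radius: int) -> np.ndarray:
    """Gram matrices over sphere neighbourhoods for every in-mask voxel.

    Returns (n_blocks, n_blocks, V).  Patterns outside the mask (or the
    grid) contribute zero, which implements sphere clipping at edges.
    Accumulation uses FFT convolution with the spherical footprint.
    """
    n_blocks = betas4d.shape[-1]
    r = int(radius)
    kern = np.zeros((2 * r + 1,) * 3)
    off = sphere_offsets(r)
    kern[off[:, 0] + r, off[:, 1] + r, off[:, 2] + r] = 1.0
    D = np.where(mask[..., None], betas4d, 0.0)
    V = int(mask.sum())
    K = np.empty((n_blocks, n_blocks, V))
    for i in range(n_blocks):
        for j in range(i, n_blocks):
            prod = D[..., i] * D[..., j]
            conv = (signal.fftconvolve(prod, kern, mode="same") if r > 0 else prod)
            K[i, j] = K[j, i] = conv[mask]
    return np.ascontiguousarray(K)


def searchlight_decode(betas4d: np.ndarray, inference_labels, mask: np.ndarray,
                       radius: int = 4, cost: float = 1.0,
                       folds=None) -> np.ndarray:
    """Whole-brain searchlight decoding accuracy map (percent).

    ``betas4d`` is (*grid, n_blocks); the accuracy of the linear SVM on
    each voxel's sphere-restricted patterns is written to that voxel.
    Voxels outside ``mask`` are NaN.  All spheres share the CV folds,
    so the per-fold SVMs are solved for every sphere simultaneously
    (a batched exact solver; per-voxel results match sklearn's SVC).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    y = np.asarray(inference_labels)
    if folds is None:
        folds = leave_two_blocks_out_folds(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary classification only")
    y_pm = np.where(y == classes[1], 1.0, -1.0)
    K = _sphere_gram_stack(np.asarray(betas4d, dtype=float), mask, radius)
    V = K.shape[2]
    # class-sort each fold's train/test indices so every fold shares the
    # same +/-1 label vector; all folds then solve in one batched call.
    def _sorted(idx):
        idx = np.asarray(idx)
        return np.concatenate([idx[y_pm[idx] > 0], idx[y_pm[idx] < 0]])

    TR = np.array([_sorted(tr) for tr, _ in folds])
    TE = np.array([_sorted(te) for _, te in folds])
    if TR.ndim != 2 or TE.ndim != 2:
        raise ValueError("all folds must hold out the same number of blocks")
    F, n_tr = TR.shape
    n_te = TE.shape[1]
    y_tr = y_pm[TR[0]]
    y_te = y_pm[TE[0]]
    Kt = np.empty((n_tr, n_tr, F * V))
    Kc = np.empty((n_te, n_tr, F * V))
    for i in range(n_tr):
        for j in range(n_tr):
            Kt[i, j] = K[TR[:, i], TR[:, j]].reshape(F * V)
        for t in range(n_te):
            Kc[t, i] = K[TE[:, t], TR[:, i]].reshape(F * V)
    dec = batch_svc_decision(Kt, y_tr, Kc, cost=cost)
    pred = np.where(dec > 0, 1.0, -1.0).reshape(n_te, F, V)
    n_correct = (pred == y_te[:, None, None]).sum(axis=(0, 1))
    acc = np.full(mask.shape, np.nan)
    acc[mask] = 100.0 * n_correct / (n_te * F)
    return acc


def searchlight_by_target(pattern_set_4d: dict, mask: np.ndarray,
                          radius: int = 4, cost: float = 1.0) -> dict:
    """Run the searchlight separately per target condition.

    ``pattern_set_4d`` maps target name -> (betas4d, inference_labels).
    """
    return {tgt: searchlight_decode(b4, labels, mask, radius=radius, cost=cost)
            for tgt, (b4, labels) in pattern_set_4d.items()}


# ---------------------------------------------------------------------------
# Group-level ROI discovery
# ---------------------------------------------------------------------------

@dataclass
class ROISet:
    """Named binary ROI masks with their discovery provenance."""

    masks: dict = field(default_factory=dict)  # name -> boolean array
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.masks)

    def names(self):
        return list(self.masks)


def _one_sample_t(data: np.ndarray) -> np.ndarray:
    """t statistic against 0 per column; +/-inf where variance is zero."""
    n = data.shape[0]
    m = data.mean(axis=0)
    var = data.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    t = np.where(var > 0, t, np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0)))
    return t


def _max_stat_threshold(data: np.ndarray, n_perm: int, alpha: float,
                        rng: np.random.Generator) -> float:
    """(1-alpha) quantile of the max-t null under subject sign flips."""
    n = data.shape[0]
    ss = (data ** 2).sum(axis=0) / n  # invariant under sign flips
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    m = signs @ data / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ss - m ** 2) * n / (n - 1)
        t = m / np.sqrt(var / n)
    t = np.where(var > 1e-300, t, np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0)))
    return float(np.quantile(t.max(axis=1), 1.0 - alpha))


def group_roi_discovery(accuracy_maps: dict, mask: np.ndarray,
                        alpha: float = 0.05, cluster_k: int = 5,
                        n_perm: int = 5000, method: str = "permutation",
                        seed: int = 0, chance: float = CHANCE_PCT) -> ROISet:
    """Voxels decoding above chance in *every* target condition.

    ``accuracy_maps`` maps target name -> (n_subjects, *grid) stack of
    per-subject searchlight accuracy maps.  Per target, each voxel's
    accuracies are tested against the 50% chance level (one-sample
    one-sided test), with familywise control over voxels by the
    max-statistic sign-flip permutation (or Bonferroni when
    ``method='bonferroni'``).  Significant voxels are intersected
    across targets; 6-connected components of at least ``cluster_k``
    voxels become named ROIs ordered by peak group accuracy.
    """
    mask = np.asarray(mask, dtype=bool)
    targets = sorted(accuracy_maps)
    n_subj = accuracy_maps[targets[0]].shape[0]
    if n_subj < 10:
        raise ValueError("need at least 10 subjects for group inference")
    rng = np.random.default_rng(seed)
    sig = np.ones(mask.shape, dtype=bool) & mask
    group_mean = np.zeros(mask.shape)
    for tgt in targets:
        stack = np.asarray(accuracy_maps[tgt], dtype=float)
        data = stack[:, mask] - chance
        t_obs = _one_sample_t(data)
        if method == "permutation":
            thr = _max_stat_threshold(data, n_perm, alpha, rng)
        elif method == "bonferroni":
            thr = stats.t.ppf(1.0 - alpha / data.shape[1], df=n_subj - 1)
        else:
            raise ValueError(f"unknown method {method!r}")
        tgt_sig = np.zeros(mask.shape, dtype=bool)
        tgt_sig[mask] = t_obs > thr
        sig &= tgt_sig
        group_mean[mask] += stack[:, mask].mean(axis=0) / len(targets)
    labels, n_comp = ndimage.label(sig, structure=ndimage.generate_binary_structure(3, 1))
    clusters = []
    for lab in range(1, n_comp + 1):
        m = labels == lab
        if m.sum() >= cluster_k:
            peak = float(group_mean[m].max())
            coord = tuple(np.argwhere(m & (group_mean == group_mean[m].max()))[0])
            clusters.append((peak, coord, m))
    if not clusters:
        warnings.warn("no cluster survived; returning an empty ROI set")
    clusters.sort(key=lambda c: (-c[0], c[1]))
    masks = {f"roi_{i + 1:02d}": m for i, (_, _, m) in enumerate(clusters)}
    prov = {"alpha": alpha, "cluster_k": cluster_k, "method": method,
            "n_perm": n_perm, "seed": seed, "targets": targets, "n_subjects": n_subj}
    return ROISet(masks=masks, provenance=prov)


# ---------------------------------------------------------------------------
# Cross-sample decoding
# ---------------------------------------------------------------------------

def _stack_group(pattern_sets) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([p.patterns for p in pattern_sets])
    y = np.concatenate([p.inference for p in pattern_sets])
    return X, y


def cross_sample_decode(group_a, group_b, cost: float = 1.0) -> tuple[float, float]:
    """Two-fold cross-sample decoding: train on one group, test the other.

    Both arguments are lists of :class:`BetaPatternSet` sharing the same
    voxel order.  Returns accuracies (A->B, B->A) in percent.
    """
    Xa, ya = _stack_group(group_a)
    Xb, yb = _stack_group(group_b)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError(f"voxel spaces differ: {Xa.shape[1]} vs {Xb.shape[1]}")
    va = {tuple(p.voxel_index) for p in group_a if p.voxel_index is not None}
    vb = {tuple(p.voxel_index) for p in group_b if p.voxel_index is not None}
    if len(va | vb) > 1:
        raise ValueError("voxel index lists are not aligned across groups")
    acc = []
    for Xtr, ytr, Xte, yte in ((Xa, ya, Xb, yb), (Xb, yb, Xa, ya)):
        pred = svc_train_predict(Xtr @ Xtr.T, ytr, Xte @ Xtr.T, cost=cost)
        acc.append(100.0 * float((pred == yte).mean()))
    return acc[0], acc[1]
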