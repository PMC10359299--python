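"""Permutation nulls, significance decisions and multiple-comparison control.

Observed statistics (group-mean decoding accuracy, cross-validated
prediction r) are compared against empirical null distributions built
by relabelling: block labels are shuffled with the *same* permutation
for every participant (decoding), or score labels are shuffled against
subjects (SVR).  A result is significant when it exceeds the null's
95th percentile; exact add-one p-values are reported alongside, and
Benjamini-Hochberg FDR corrects across the family of ROI-wise tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoding import decode_patterns, leave_two_blocks_out_folds
from .prediction import lopo_svr


@dataclass
class NullDistribution:
    """Empirical null of a statistic under label permutation."""

    values: np.ndarray
    statistic: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("null distribution is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null distribution contains non-finite values")

    @property
    def n_perm(self) -> int:
        return self.values.size

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))


def null_decoding(pattern_sets, n_perm: int = 1000, seed: int = 0,
                  cost: float = 1.0) -> NullDistribution:
    """Null of the group-mean ROI decoding accuracy.

    Each permutation draws one reordering of the block positions and
    applies the *same* reordering to every participant's own label
    sequence (participants must share the block count and class
    counts), re-runs the leave-two-blocks-out decoding per participant,
    and stores the group mean.
    """
    structures = {(len(p.inference), int((p.inference == "why").sum()))
                  for p in pattern_sets}
    if len(structures) != 1:
        raise ValueError("participants must share the block structure "
                         "(same number of blocks and class counts)")
    n_blocks = len(pattern_sets[0].inference)
    grams = [p.patterns @ p.patterns.T for p in pattern_sets]
    rng = np.random.default_rng(seed)
    vals = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n_blocks)
        accs = []
        for p, g in zip(pattern_sets, grams):
            y = np.asarray(p.inference)[perm]
            folds = leave_two_blocks_out_folds(y)
            accs.append(decode_patterns(p.patterns, y, folds=folds, cost=cost, gram=g))
        vals[k] = float(np.mean(accs))
    return NullDistribution(values=vals, statistic="group_mean_accuracy", seed=seed)


def null_svr(features: np.ndarray, labels: np.ndarray, n_perm: int = 1000,
             seed: int = 0, nu: float = 0.5, cost: float = 1.0,
             predictor=None) -> NullDistribution:
    """Null of the cross-validated prediction r under label shuffling.

    Per permutation the score labels are shuffled against the feature
    rows and the full cross-validated pipeline re-run.  ``predictor``
    defaults to LOPO nu-SVR; pass a callable (features, labels) ->
    PredictionResult to build nulls for other schemes (e.g. the
    cross-sample fit).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_perm)
    if predictor is None:
        gram = X @ X.T
        for k in range(n_perm):
            vals[k] = lopo_svr(X, y[rng.permutation(y.size)], nu=nu, cost=cost,
                               gram=gram).r
    else:
        for k in range(n_perm):
            vals[k] = predictor(X, y[rng.permutation(y.size)]).r
    return NullDistribution(values=vals, statistic="prediction_r", seed=seed)


def perm_pvalue(observed: float, null: NullDistribution,
                percentile: float = 95.0) -> tuple[float, bool]:
    """Add-one one-sided p-value and the percentile-rule decision.

    p = (1 + #{null >= observed}) / (n_perm + 1); the result counts as
    significant only when the observed statistic strictly exceeds the
    null's ``percentile`` (95th by default).
    """
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    n = null.n_perm
    p = (1.0 + float((null.values >= observed).sum())) / (n + 1.0)
    significant = observed > null.percentile(percentile)
    return p, significant


def fdr_correct(pvalues, q: float = 0.05,
                method: str = "bh") -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg (or Benjamini-Yekutieli) step-up correction.

    Returns (reject flags, adjusted p-values).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    reject, p_adj = multipletests(p, alpha=q, method=key)[:2]
    return reject, p_adj


def group_compare(a, b, equal_var: bool = True,
                  alpha: float = 0.05) -> tuple[float, float, float, tuple[float, float]]:
    """Two-sample t test (pooled by default) with a confidence interval.

    Returns (t, df, two-tailed p, CI of the mean difference).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    return float(res.statistic), float(res.df), float(res.pvalue), (float(ci.low), float(ci.high))
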