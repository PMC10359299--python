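"""Motion quality control and behavioral performance summaries.

Motion screening follows the low-pass-filter-then-FD convention:
rigid-body traces are zero-phase Butterworth filtered (order 5,
0.2 Hz) to suppress respiratory pseudo-motion before framewise
displacement is computed, and participants whose FD percentile pair
(50th, 95th) falls outside the main density cluster are flagged by
DBSCAN.  Spike frames for the GLM come from separate translation /
rotation differential thresholds (0.5 mm, 0.5 deg) and a DVARS rule
(> mean + 2.5 SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.cluster import DBSCAN

HEAD_RADIUS_MM = 50.0


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def butterworth_lowpass(series: np.ndarray, sampling_hz: float,
                        cutoff_hz: float = 0.2, order: int = 5) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 0."""
    series = np.asarray(series, dtype=float)
    nyquist = sampling_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    if series.shape[0] <= 3 * order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sampling_hz, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def framewise_displacement(motion: np.ndarray,
                           head_radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
    """FD_t = sum |delta translation| + r * sum |delta rotation| (mm).

    ``motion`` has six columns: three translations in mm and three
    rotations in radians, converted to arc length on a sphere of
    ``head_radius_mm``.  The first frame has FD 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must have exactly 6 columns")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def dvars(series2d: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """RMS over in-mask voxels of the temporal signal derivative.

    ``series2d`` is (n_volumes, n_voxels); ``mask`` a boolean voxel
    selector.  First frame is 0.
    """
    series2d = np.asarray(series2d, dtype=float)
    if mask is not None:
        mask = np.asarray(mask).reshape(-1).astype(bool)
        if not mask.any():
            raise ValueError("mask is empty")
        series2d = series2d[:, mask]
    if series2d.shape[1] == 0:
        raise ValueError("no voxels to compute DVARS over")
    d = np.diff(series2d, axis=0)
    return np.concatenate([[0.0], np.sqrt(np.mean(d ** 2, axis=1))])


def spike_frames(motion: np.ndarray, series2d: np.ndarray | None = None,
                 mask: np.ndarray | None = None,
                 translation_mm: float = 0.5, rotation_deg: float = 0.5,
                 dvars_sd: float = 2.5) -> np.ndarray:
    """Frames needing a spike regressor in the GLM.

    A frame is flagged when its summed absolute translation
    differential exceeds ``translation_mm``, its summed absolute
    rotation differential exceeds ``rotation_deg``, or (when a series
    is supplied) its raw DVARS exceeds mean + ``dvars_sd`` SD of the
    run's DVARS.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must have exactly 6 columns")
    d = np.diff(motion, axis=0)
    trans = np.concatenate([[0.0], np.abs(d[:, :3]).sum(axis=1)])
    rot = np.concatenate([[0.0], np.abs(np.degrees(d[:, 3:])).sum(axis=1)])
    bad = (trans > translation_mm) | (rot > rotation_deg)
    if series2d is not None:
        dv = dvars(series2d, mask)
        bad |= dv > dv.mean() + dvars_sd * dv.std()
    return np.flatnonzero(bad)


@dataclass
class MotionQCReport:
    """Per-subject motion summary used for exclusion decisions."""

    fd: np.ndarray  # mm, per frame (after low-pass filtering)
    fd_p50: float
    fd_p95: float
    dvars: np.ndarray | None = None
    spikes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    outlier: bool | None = None

    def __post_init__(self):
        if np.any(self.fd < 0):
            raise ValueError("FD must be non-negative")
        if self.fd_p50 > self.fd_p95:
            raise ValueError("percentiles out of order")
        if self.spikes.size and (self.spikes.min() < 0 or self.spikes.max() >= self.fd.size):
            raise ValueError("spike index outside the scan")


def motion_qc(motion: np.ndarray, sampling_hz: float,
              series2d: np.ndarray | None = None,
              mask: np.ndarray | None = None,
              lowpass_hz: float = 0.2, order: int = 5) -> MotionQCReport:
    """Filter the motion trace, compute FD percentiles and spike frames."""
    filtered = butterworth_lowpass(motion, sampling_hz, lowpass_hz, order)
    fd = framewise_displacement(filtered)
    dv = dvars(series2d, mask) if series2d is not None else None
    sp = spike_frames(motion, series2d, mask)
    return MotionQCReport(fd=fd, fd_p50=float(np.percentile(fd, 50)),
                          fd_p95=float(np.percentile(fd, 95)), dvars=dv, spikes=sp)


def flag_outlier_participants(fd_p50: np.ndarray, fd_p95: np.ndarray,
                              eps: float | None = None,
                              min_samples: int = 4) -> np.ndarray:
    """Density-based flagging of high-motion participants.

    DBSCAN clusters the 2-D (FD p50, FD p95) points; everyone outside
    the largest cluster is flagged.  By default ``eps`` is 1.5 times
    the median distance to the ``min_samples``-th nearest neighbour
    (the k-distance convention; scale-free, and deterministic given
    the inputs).
    """
    pts = np.column_stack([np.asarray(fd_p50, float), np.asarray(fd_p95, float)])
    n = pts.shape[0]
    if n < 5:
        raise ValueError("need at least 5 participants for density-based flagging")
    if eps is None:
        d2 = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d2, np.inf)
        k = min(min_samples, n - 1)
        kth = np.sort(d2, axis=1)[:, k - 1]
        eps = 1.5 * float(np.median(kth))
        if eps <= 0:
            return np.zeros(n, dtype=bool)  # all points coincide
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
    valid = labels[labels >= 0]
    if valid.size == 0:
        return np.ones(n, dtype=bool)
    main = np.bincount(valid).argmax()
    return labels != main


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' = z(hit rate) - z(false-alarm rate)."""
    if not (0 < hit_rate < 1 and 0 < fa_rate < 1):
        raise ValueError("rates must lie strictly in (0, 1); apply a correction first")
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def dprime(n_hit: int, n_miss: int, n_fa: int, n_cr: int,
           correction: str | None = "loglinear") -> float:
    """d' from raw counts, with the log-linear 0/1-rate correction.

    The log-linear rule adds 0.5 to each cell and 1 to each
    denominator, keeping z finite when a rate is 0 or 1.
    """
    if correction == "loglinear":
        hr = (n_hit + 0.5) / (n_hit + n_miss + 1.0)
        far = (n_fa + 0.5) / (n_fa + n_cr + 1.0)
    elif correction is None:
        hr = n_hit / (n_hit + n_miss)
        far = n_fa / (n_fa + n_cr)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return dprime_from_rates(hr, far)


def boxcox_scores(values: np.ndarray, lmbda: float | None = None):
    """Box-Cox transform (lambda by maximum likelihood when not given)."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lmbda is None:
        return stats.boxcox(values)
    return stats.boxcox(values, lmbda=lmbda), lmbda


def behavioral_summary(trials: pd.DataFrame, rt_sd_cutoff: float = 3.0) -> pd.DataFrame:
    """Per-condition accuracy, d' and trimmed mean RT.

    ``trials`` needs columns ``condition``, ``answer`` ('yes'/'no'),
    ``response`` ('yes'/'no' or NA for omissions) and ``rt`` (s).
    No-response trials are dropped from the accuracy denominator; RTs
    more than ``rt_sd_cutoff`` SDs from the condition mean are trimmed.
    d' treats 'yes' ground-truth trials as signal.
    """
    out = []
    for cond, grp in trials.groupby("condition", sort=True):
        responded = grp[grp["response"].notna()]
        n_scorable = len(responded)
        omission_pct = 100.0 * (len(grp) - n_scorable) / len(grp) if len(grp) else np.nan
        if n_scorable == 0:
            warnings.warn(f"condition {cond!r} has no scorable trials")
            out.append({"condition": cond, "n_trials": len(grp), "accuracy_pct": np.nan,
                        "dprime": np.nan, "mean_rt": np.nan, "omission_pct": omission_pct})
            continue
        correct = responded["answer"] == responded["response"]
        acc = 100.0 * correct.mean()
        sig = responded["answer"] == "yes"
        n_hit = int((sig & (responded["response"] == "yes")).sum())
        n_miss = int(sig.sum()) - n_hit
        n_fa = int((~sig & (responded["response"] == "yes")).sum())
        n_cr = int((~sig).sum()) - n_fa
        dp = dprime(n_hit, n_miss, n_fa, n_cr) if sig.any() and (~sig).any() else np.nan
        rts = responded["rt"].to_numpy(dtype=float)
        rts = rts[np.isfinite(rts)]
        if rts.size:
            keep = np.abs(rts - rts.mean()) <= rt_sd_cutoff * (rts.std() or np.inf)
            mean_rt = float(rts[keep].mean())
        else:
            mean_rt = np.nan
        out.append({"condition": cond, "n_trials": len(grp), "accuracy_pct": acc,
                    "dprime": dp, "mean_rt": mean_rt, "omission_pct": omission_pct})
    return pd.DataFrame(out)
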