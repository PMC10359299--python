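"""Synthetic multi-subject block-design BOLD studies.

The generator produces data *after* spatial preprocessing: every
subject lives on a common voxel grid, so no realignment, normalisation
or smoothing is modelled.  Signal is planted as multivoxel patterns:

* a why-vs-how condition pattern inside designated regions, mixed from
  a group-shared component and a subject-specific component
  (``shared_fraction`` controls the mix, enabling cross-sample
  transfer tests);
* a linear encoding of a behavioral score in the why-how contrast
  pattern of one region (amplitude ``score_encoding_gain`` per unit
  z-score), which is what the individual-difference prediction should
  recover;
* i.i.d. Gaussian noise, optional AR(1) temporal correlation, optional
  low-order polynomial drift, and six-column motion traces with
  occasional step-displacement spikes.

Time courses use the same HRF-convolved block regressors the GLM
fits, so with zero noise the GLM recovers the planted amplitudes
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy.signal import lfilter

from .design import BlockDesign
from .glm import block_regressors

__all__ = ["GroundTruth", "SubjectData", "box_region", "default_ground_truth",
           "sample_behavior", "simulate_subject", "simulate_study"]


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters shared by all subjects of a study."""

    grid: tuple[int, int, int]
    voxel_size_mm: float = 2.5
    planted_regions: dict = field(default_factory=dict)  # name -> boolean mask
    condition_effect_gain: float = 0.4
    shared_fraction: float = 0.5
    encoding_region: str | None = None
    score_encoding_gain: float = 0.1
    task_amplitude: float = 1.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    ar_coef: float = 0.0
    baseline: float = 100.0
    seed: int = 0  # seeds the group-shared patterns

    def __post_init__(self):
        if self.condition_effect_gain < 0 or self.score_encoding_gain < 0:
            raise ValueError("gains must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, mask in self.planted_regions.items():
            if np.asarray(mask).shape != tuple(self.grid):
                raise ValueError(f"region {name!r} does not match the grid")
        if self.encoding_region is not None \
                and self.encoding_region not in self.planted_regions:
            raise ValueError(f"unknown encoding region {self.encoding_region!r}")


@dataclass
class SubjectData:
    """One simulated (or loaded) subject."""

    series: np.ndarray  # (*grid, n_volumes)
    motion: np.ndarray  # (n_volumes, 6): 3 translations mm, 3 rotations rad
    design: BlockDesign
    behavior: pd.Series | None = None
    seed: int | None = None

    def __post_init__(self):
        n = self.design.n_volumes
        if self.series.shape[-1] != n:
            raise ValueError("series length does not match the design")
        if self.motion.shape != (n, 6):
            raise ValueError(f"motion must be ({n}, 6)")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")

    @property
    def grid(self) -> tuple[int, ...]:
        return self.series.shape[:-1]

    @property
    def series2d(self) -> np.ndarray:
        """(n_volumes, n_voxels) view for GLM fitting."""
        n = self.series.shape[-1]
        return self.series.reshape(-1, n).T


def box_region(grid, corner, size) -> np.ndarray:
    """Axis-aligned box of voxels as a boolean mask."""
    mask = np.zeros(grid, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    mask[sl] = True
    if not mask.any() or mask.sum() != int(np.prod(size)):
        raise ValueError("region extends outside the grid")
    return mask


def default_ground_truth(grid=(24, 24, 24), **overrides) -> GroundTruth:
    """Two disjoint planted regions; the first also encodes the score."""
    size = tuple(max(2, g // 4) for g in grid)
    corner_a = tuple(g // 6 for g in grid)
    corner_b = tuple(g - g // 6 - s for g, s in zip(grid, size))
    regions = {
        "region_a": box_region(grid, corner_a, size),
        "region_b": box_region(grid, corner_b, size),
    }
    base = dict(grid=tuple(grid), planted_regions=regions,
                encoding_region="region_a")
    base.update(overrides)
    return GroundTruth(**base)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

_GROUP_TRAIT = {  # (mean, sd) of the autism-trait questionnaire per group
    "DS": (15.55, 2.73), "RS1": (13.35, 4.53), "RS2": (50.44, 8.38),
    "ASD": (15.55, 2.73),
}


def sample_behavior(n_subjects: int, seed: int = 0, group: str = "DS",
                    target_corr: float = 0.16,
                    sni_mean: float = 16.68, sni_sd: float = 10.23,
                    trait_mean: float | None = None, trait_sd: float | None = None,
                    iq_mean: float = 108.14, iq_sd: float = 10.14) -> pd.DataFrame:
    """Sample a per-subject behavioral table via a Gaussian copula.

    The number of social contacts (SNI network size) is lognormal
    (right-skewed count data), rounded to a non-negative integer;
    autism-trait and IQ scores are rounded normals.  ``target_corr``
    sets the latent correlation between trait and SNI scores (the
    empirically observed association is weak and non-significant); IQ
    is independent of both.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if not abs(target_corr) < 1:
        raise ValueError("|target_corr| must be < 1")
    if group not in _GROUP_TRAIT:
        raise ValueError(f"unknown group {group!r}")
    t_mean, t_sd = _GROUP_TRAIT[group]
    trait_mean = t_mean if trait_mean is None else trait_mean
    trait_sd = t_sd if trait_sd is None else trait_sd
    corr = np.array([[1.0, target_corr, 0.0],
                     [target_corr, 1.0, 0.0],
                     [0.0, 0.0, 1.0]])
    if np.linalg.eigvalsh(corr).min() < -1e-12:
        raise ValueError("correlation matrix is not positive semidefinite")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(3), corr, size=n_subjects,
                                method="cholesky")
    sigma2 = np.log1p((sni_sd / sni_mean) ** 2)
    mu = np.log(sni_mean) - sigma2 / 2.0
    sni = np.maximum(np.rint(np.exp(mu + np.sqrt(sigma2) * z[:, 0])), 0).astype(int)
    trait = np.rint(trait_mean + trait_sd * z[:, 1])
    iq = np.rint(iq_mean + iq_sd * z[:, 2])
    table = pd.DataFrame({
        "subject": [f"{group.lower()}{i + 1:03d}" for i in range(n_subjects)],
        "group": group,
        "sni_size": sni,
        "aq_or_srs": trait,
        "iq": iq,
    })
    if group == "ASD":
        table["ados_sa"] = np.clip(np.rint(7.52 + 1.50 * rng.standard_normal(n_subjects)), 0, 10)
        table["ados_rrb"] = np.clip(np.rint(6.86 + 2.51 * rng.standard_normal(n_subjects)), 0, 10)
    return table


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _group_patterns(truth: GroundTruth) -> dict:
    """Group-shared condition/encoding patterns, fixed by truth.seed."""
    rng = np.random.default_rng(truth.seed)
    out = {}
    for name in sorted(truth.planted_regions):
        nvox = int(np.asarray(truth.planted_regions[name]).sum())
        cond = _unit(rng.standard_normal(nvox))
        enc = _unit(rng.standard_normal(nvox))
        out[name] = (cond, enc)
    return out


def simulate_subject(design: BlockDesign, truth: GroundTruth,
                     behavior: pd.Series | None = None, seed: int = 0,
                     score_z: float = 0.0, n_motion_spikes: int = 2,
                     spike_magnitude_mm: float = 1.0) -> SubjectData:
    """Forward-simulate one subject's 4D series and motion trace.

    The why-how amplitude difference inside each planted region equals
    ``condition_effect_gain`` times a unit-norm pattern mixed from the
    group and subject components; the encoding region additionally
    carries ``score_encoding_gain * score_z`` times the group encoding
    pattern.  Identical (design, truth, seed, score_z) give bit-identical
    output.
    """
    rng = np.random.default_rng(seed)
    grid = tuple(truth.grid)
    n_vox = int(np.prod(grid))
    n_vol = design.n_volumes
    X_task, names = block_regressors(design)
    n_blocks = X_task.shape[1]

    amp = np.zeros((n_blocks, n_vox))
    shared = _group_patterns(truth)
    sf = truth.shared_fraction
    sign = np.array([+0.5 if b.inference == "why" else -0.5 for b in design.blocks])
    social = np.array([b.target in ("faces", "hands") for b in design.blocks])
    for name in sorted(truth.planted_regions):
        flat_idx = np.flatnonzero(np.asarray(truth.planted_regions[name]).ravel())
        cond_group, enc_group = shared[name]
        cond_subj = _unit(sf * cond_group + (1.0 - sf) * _unit(rng.standard_normal(flat_idx.size)))
        pattern = truth.condition_effect_gain * cond_subj
        amp[:, flat_idx] += truth.task_amplitude + sign[:, None] * pattern[None, :]
        if name == truth.encoding_region:
            # the behavioral score modulates the why-how contrast pattern of
            # *social* inference only; nonsocial blocks carry no encoding
            enc = truth.score_encoding_gain * score_z * enc_group
            amp[:, flat_idx] += (sign * social)[:, None] * enc[None, :]

    series = truth.baseline + X_task @ amp
    if truth.noise_sd > 0:
        noise = rng.normal(0.0, truth.noise_sd, size=(n_vol, n_vox))
        if truth.ar_coef:
            noise = lfilter([np.sqrt(1.0 - truth.ar_coef ** 2)],
                            [1.0, -truth.ar_coef], noise, axis=0)
        series = series + noise
    if truth.drift_amplitude > 0:
        t = np.linspace(-1.0, 1.0, n_vol)
        coefs = rng.normal(0.0, truth.drift_amplitude, size=(3, n_vox))
        series = series + npoly.polyval(t, coefs).T

    motion = np.cumsum(rng.normal(0.0, [0.02] * 3 + [4e-4] * 3, size=(n_vol, 6)), axis=0)
    if n_motion_spikes > 0:
        frames = rng.choice(np.arange(5, n_vol - 5), size=n_motion_spikes, replace=False)
        for fr in frames:
            motion[fr:, 0] += spike_magnitude_mm * rng.choice([-1.0, 1.0])
    return SubjectData(series=np.ascontiguousarray(series.T.reshape(*grid, n_vol)),
                       motion=motion, design=design, behavior=behavior, seed=seed)


def simulate_study(design: BlockDesign, truth: GroundTruth, n_subjects: int,
                   seed: int = 0, group: str = "DS",
                   encoded_score: str = "sni_size",
                   behavior: pd.DataFrame | None = None,
                   randomize_order: bool = True,
                   **subject_kwargs) -> list[SubjectData]:
    """Simulate a full sample with the score encoding z-scored in-sample.

    With ``randomize_order`` (default) every participant gets an
    independent balanced why/how order on the common block timing,
    which keeps the block labels exchangeable with respect to the
    GLM's temporal estimation noise across the sample.
    """
    from .design import permute_block_labels

    if behavior is None:
        behavior = sample_behavior(n_subjects, seed=seed, group=group)
    if len(behavior) != n_subjects:
        raise ValueError("behavior table size does not match n_subjects")
    scores = behavior[encoded_score].to_numpy(dtype=float)
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_subjects) >> 1
    out = []
    for i in range(n_subjects):
        d_i = (permute_block_labels(design, int(seeds[2 * i + 1]))
               if randomize_order else design)
        out.append(simulate_subject(d_i, truth, behavior=behavior.iloc[i],
                                    seed=int(seeds[2 * i]), score_z=float(z[i]),
                                    **subject_kwargs))
    return out
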