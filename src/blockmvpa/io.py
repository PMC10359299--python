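"""File formats, study configuration and provenance records.

Volumes travel as NIfTI-1 (nibabel), designs as BIDS-style events TSV,
behavior as CSV, results and null distributions as JSON, and the study
configuration as YAML.  Voxel indexing is 0-based in (x, y, z) order;
world coordinates live in the NIfTI affine, and every mask must share
the data's grid exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import Block, BlockDesign, Trial


class AlignmentError(ValueError):
    """Two volumes do not share a voxel grid."""


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None,
               voxel_size: float = 2.5) -> None:
    if affine is None:
        affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def check_alignment(shape_a, affine_a, shape_b, affine_b) -> None:
    """Raise AlignmentError unless both grids match exactly."""
    if tuple(shape_a[:3]) != tuple(shape_b[:3]) or not np.allclose(affine_a, affine_b):
        raise AlignmentError(
            "grids differ:\n"
            f"  a: shape {tuple(shape_a[:3])}, affine diag {np.diag(affine_a)[:3]}\n"
            f"  b: shape {tuple(shape_b[:3])}, affine diag {np.diag(affine_b)[:3]}")


def load_masked_series(series_path, mask_path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a 4D series and mask, checking their grids; returns
    (series (*grid, n_vol), mask bool, affine)."""
    series, aff_s = load_nifti(series_path)
    mask, aff_m = load_nifti(mask_path)
    check_alignment(series.shape, aff_s, mask.shape, aff_m)
    return series, mask.astype(bool), aff_s


# ---------------------------------------------------------------------------
# Events / behavior tables
# ---------------------------------------------------------------------------

def write_events_tsv(path, design: BlockDesign) -> None:
    design.to_events().to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path, tr: float, n_volumes: int) -> BlockDesign:
    """Reconstruct a BlockDesign from a BIDS-style events table."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    for col in ("onset", "duration", "trial_type", "block"):
        if col not in df.columns:
            raise ValueError(f"events table lacks the {col!r} column")
    blocks = []
    for bi, grp in df.groupby("block", sort=True):
        inference, target = str(grp["trial_type"].iloc[0]).split("_", 1)
        trials = tuple(Trial(onset=float(r.onset), response_window=float(r.duration))
                       for r in grp.itertuples())
        onset = float(grp["onset"].min())
        offset = float((grp["onset"] + grp["duration"]).max())
        blocks.append(Block(inference=inference, target=target, onset=onset,
                            offset=offset, trials=trials))
    return BlockDesign(blocks=tuple(blocks), tr=tr, n_volumes=n_volumes)


def write_behavior_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_behavior_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if table["subject"].duplicated().any():
        raise ValueError("duplicated subject ids in behavior table")
    return table


def write_ground_truth_json(path, truth) -> None:
    """Serialise generator parameters (regions as flat voxel index lists)."""
    import dataclasses as _dc

    d = _dc.asdict(truth)
    d["grid"] = list(truth.grid)
    d["planted_regions"] = {
        name: np.flatnonzero(np.asarray(mask).ravel()).tolist()
        for name, mask in truth.planted_regions.items()}
    write_json(path, d)


def read_ground_truth_json(path):
    from .synthetic import GroundTruth

    d = read_json(path)
    grid = tuple(d["grid"])
    regions = {}
    for name, idx in d["planted_regions"].items():
        mask = np.zeros(int(np.prod(grid)), dtype=bool)
        mask[np.asarray(idx, dtype=int)] = True
        regions[name] = mask.reshape(grid)
    d["grid"] = grid
    d["planted_regions"] = regions
    return GroundTruth(**d)


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Every fixed constant of the pipeline in one (YAML-round-trippable) place."""

    # grid / design
    grid: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.5
    tr: float = 1.0
    n_blocks_per_condition: int = 4
    stimuli_per_block: int = 8
    targets: tuple[str, ...] = ("faces", "hands")
    n_subjects: int = 12
    # generator
    condition_effect_gain: float = 0.4
    score_encoding_gain: float = 0.1
    shared_fraction: float = 0.5
    noise_sd: float = 1.0
    # GLM
    highpass_cutoff_s: float = 100.0
    robust_wls: bool = True
    # QC
    fd_translation_mm: float = 0.5
    fd_rotation_deg: float = 0.5
    dvars_sd: float = 2.5
    butterworth_order: int = 5
    butterworth_cutoff_hz: float = 0.2
    # decoding
    searchlight_radius: int = 4
    svm_cost: float = 1.0
    cluster_k: int = 5
    alpha: float = 0.05
    # prediction
    svr_nu: float = 0.5
    svr_cost: float = 1.0
    # inference
    n_perm: int = 1000
    significance_percentile: float = 95.0
    fdr_q: float = 0.05
    # seeds
    seed: int = 0

    def __post_init__(self):
        self.grid = tuple(self.grid)
        self.targets = tuple(self.targets)
        for name in ("tr", "fd_translation_mm", "fd_rotation_deg", "dvars_sd",
                     "butterworth_cutoff_hz", "svm_cost", "svr_cost", "alpha",
                     "fdr_q", "highpass_cutoff_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 50.0 < self.significance_percentile < 100.0:
            raise ValueError("significance percentile must lie in (50, 100)")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        d["targets"] = list(self.targets)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        d["targets"] = list(self.targets)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunRecord:
    config_digest: str
    seed: int
    stage: str
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timestamp: float = field(default_factory=time.time)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_run_record(config: StudyConfig, stage: str, output_paths) -> RunRecord:
    return RunRecord(config_digest=config.digest(), seed=config.seed, stage=stage,
                     outputs={str(p): file_digest(p) for p in output_paths})


def write_json(path, payload) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=_default))


def read_json(path):
    return json.loads(Path(path).read_text())
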