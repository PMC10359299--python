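import numpy as np
import pytest

import blockmvpa as bm
from blockmvpa.glm import build_design_matrix, fit_glm


@pytest.fixture(scope="session")
def ds_design():
    """Discovery-sample layout: 4 blocks/condition, 8 stimuli, 2 targets."""
    return bm.make_block_design(4, 8, targets=("faces", "hands"), seed=0)


@pytest.fixture(scope="session")
def single_target_design():
    """4 why + 4 how blocks of one target; 16 CV folds."""
    return bm.make_block_design(4, 8, targets=("faces",), seed=0)


@pytest.fixture(scope="session")
def small_truth():
    """One 216-voxel region filling a compact grid; encodes the score."""
    grid = (6, 6, 6)
    return bm.GroundTruth(grid=grid,
                          planted_regions={"roi": np.ones(grid, dtype=bool)},
                          encoding_region="roi", seed=7)


@pytest.fixture(scope="session")
def fitted_subject(ds_design, small_truth):
    """One simulated subject with its GLM fit (shared across tests)."""
    subject = bm.simulate_subject(ds_design, small_truth, seed=11)
    X = build_design_matrix(subject.design, motion=subject.motion)
    return subject, X, fit_glm(subject.series2d, X)
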