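import numpy as np
import pandas as pd
import pytest

from ssmpca.imageio import BrainMask
from ssmpca.simulate import SimulationConfig, simulate_cohort
from ssmpca.ssm import DataMatrix, derive_ssm


@pytest.fixture
def line_mask():
    """Three in-mask voxels on a 3×1×1 grid."""
    return BrainMask(np.ones((3, 1, 1)))


@pytest.fixture
def toy_matrix(line_mask):
    """The 3-voxel / 2-subject worked example: columns (1,2,3) and (3,2,1)."""
    return DataMatrix(
        np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]),
        line_mask,
        ["s1", "s2"],
    )


@pytest.fixture
def toy_model(toy_matrix):
    return derive_ssm(toy_matrix)


def make_manifest(
    n_per_group=(2, 2), visits=("V1",), conditions=("EC", "EO"), path_fmt="{s}_{v}_{c}"
) -> pd.DataFrame:
    rows = []
    groups = ["EC-EO"] * n_per_group[0] + ["EO-EC"] * n_per_group[1]
    for j, g in enumerate(groups):
        s = f"sub-{j + 1:02d}"
        for v in visits:
            for c in conditions:
                rows.append(
                    {
                        "subject_id": s,
                        "group": g,
                        "visit": v,
                        "condition": c,
                        "path": path_fmt.format(s=s, v=v, c=c),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def small_cohort():
    """Default-condition synthetic cohort on a reduced grid (fast)."""
    cfg = SimulationConfig.from_targets(
        0.6, 1.2, grid_shape=(10, 12, 10), seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture
def clean_cohort():
    """Single-visit cohort with no session or voxel noise (noiseless limit)."""
    cfg = SimulationConfig(
        grid_shape=(10, 12, 10),
        loading_mean=0.8,
        loading_sd=0.9,
        session_noise_sd=0.0,
        voxel_noise_sd=0.0,
        n_visits=1,
        scanner_gain=(1.0,),
        seed=5,
    )
    return simulate_cohort(cfg)
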