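import numpy as np
import pandas as pd
import pytest

from fosnet.synthetic import (
    CohortDesign,
    NeurogenesisEffectProfile,
    PlantedStructure,
    default_structure,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def small_design():
    return CohortDesign(n_per_group=6, seed=11)


@pytest.fixture
def small_profile():
    return NeurogenesisEffectProfile()


@pytest.fixture
def small_structure(small_design, small_profile):
    return default_structure(small_design, small_profile)


@pytest.fixture
def flat_blocks_structure():
    """Two blocks of three regions, shared across groups."""
    return PlantedStructure(
        blocks={"DG": 0, "CA1": 0, "CA3": 0, "EC": 1, "RSC": 1, "BLA": 1},
        within_block_r=0.9,
        between_block_r=0.2,
        region_means={r: 100.0 for r in ("DG", "CA1", "CA3", "EC", "RSC", "BLA")},
        density_noise_sd=20.0,
    )


def random_activity_table(rng, n_subjects=6, regions=("DG", "CA1", "CA3", "EC"), **meta):
    """Random regional activity table for one group."""
    meta = {"treatment": "control", "age": 4, "sex": "male", **meta}
    rows = []
    for i in range(n_subjects):
        row = {"subject_id": f"s{i:02d}", **meta}
        row.update({r: float(v) for r, v in zip(regions, rng.normal(100, 20, len(regions)))})
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def activity_table(rng):
    return random_activity_table(rng)
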