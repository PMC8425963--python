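import numpy as np
import pandas as pd
import pytest

from prestim.synth import StudyDesign, SubjectProfile, grid_layout


@pytest.fixture
def paper_design():
    """The full session protocol (5 blocks, 60 test / 30 control per direction)."""
    return StudyDesign()


@pytest.fixture
def tiny_design():
    """Reduced session for fast raw-epoch tests."""
    return StudyDesign(n_blocks=1, test_per_block_per_direction=10, control_per_block_per_direction=5)


@pytest.fixture
def layout4():
    return grid_layout(4, 4)


@pytest.fixture
def neutral_profile():
    return SubjectProfile(subject_id="S00", base_illusion_rate=0.5)


@pytest.fixture
def toy_trials():
    """Hand-enumerable 8-trial labeled table: per direction 2 ILL, 1 no-ILL,
    1 CTRL-correct; inward also differs in RT."""
    rows = []
    for direction in ("inward", "outward"):
        rows += [
            {"condition": "test", "direction": direction, "response": "intermediate", "rt": 0.7},
            {"condition": "test", "direction": direction, "response": "intermediate", "rt": 0.9},
            {"condition": "test", "direction": direction, "response": "not-intermediate", "rt": 0.8},
            {"condition": "control", "direction": direction, "response": "intermediate", "rt": 0.5},
        ]
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(len(df)))
    return df
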