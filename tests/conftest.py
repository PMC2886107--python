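import numpy as np
import pandas as pd
import pytest

import beepop as bp


@pytest.fixture(scope="session")
def study_samples():
    return bp.enumerate_samples(bp.STUDY_ROSTER)


@pytest.fixture(scope="session")
def study_design(study_samples):
    """One 58-block design shared across the suite (seeded, so stable)."""
    return bp.generate_design(study_samples, seed=11)


@pytest.fixture(scope="session")
def tiny_roster():
    return [
        bp.PopulationSpec("A", 1, 50.0),
        bp.PopulationSpec("B", 1, 10.0),
        bp.PopulationSpec("C", 1, -30.0),
    ]


@pytest.fixture(scope="session")
def tiny_design(tiny_roster):
    return bp.generate_design(bp.enumerate_samples(tiny_roster), seed=0)


def make_matrix(values, block_ids=("b01",), channels=("light", "medium", "heavy")):
    """Small ratio matrix helper: values is (n_proteins, n_blocks*3)."""
    cols = pd.MultiIndex.from_product([list(block_ids), list(channels)],
                                      names=["block_id", "channel"])
    arr = np.asarray(values, float)
    idx = pd.Index([f"P{i + 1:04d}" for i in range(arr.shape[0])], name="protein_id")
    return pd.DataFrame(arr, index=idx, columns=cols)
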