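import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cxragree import StudyDataset

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def make_dataset(truth, calls_a, calls_b, finding="pneumothorax",
                 reader_a="radiologist", reader_b="ai"):
    """Build a one-finding StudyDataset from call vectors (None = unavailable)."""
    n = len(truth)
    frame = pd.DataFrame(
        {
            "case_id": [f"c{i}" for i in range(n)],
            "finding": finding,
            "truth": np.asarray(truth, dtype="int8"),
            reader_a: pd.array(calls_a, dtype="Int8"),
            reader_b: pd.array(calls_b, dtype="Int8"),
        }
    )
    return StudyDataset(frame, readers=[reader_a, reader_b], findings=[finding])


@pytest.fixture
def toy_dataset():
    """Six hand-countable cases: truth 1,1,1,0,0,0."""
    return make_dataset(
        truth=[1, 1, 1, 0, 0, 0],
        calls_a=[1, 0, 1, 0, 1, 0],
        calls_b=[1, 1, 0, 0, 0, 1],
    )


@pytest.fixture
def na_dataset():
    """Four cases with one unavailable AI call."""
    return make_dataset(
        truth=[1, 1, 0, 0],
        calls_a=[1, 0, 0, 1],
        calls_b=[1, None, 0, 0],
    )
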