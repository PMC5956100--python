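import numpy as np
import pandas as pd
import pytest

from devcoexpr.types import CountMatrix, SampleMetadata


@pytest.fixture
def small_counts() -> CountMatrix:
    data = pd.DataFrame(
        [[10, 20, 30, 40], [5, 5, 5, 5], [0, 1, 2, 3]],
        index=["geneA", "geneB", "geneC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CountMatrix(data)


@pytest.fixture
def two_stage_meta() -> SampleMetadata:
    return SampleMetadata(
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}, ("A", "B")
    )


@pytest.fixture
def study_meta() -> SampleMetadata:
    """The 28-sample, 4-stage replicate structure of the study design."""
    stage_of = {}
    for stage, n in zip(("E11", "E12", "E13", "E14"), (6, 7, 9, 6)):
        for i in range(n):
            stage_of[f"{stage}_r{i + 1}"] = stage
    return SampleMetadata(stage_of, ("E11", "E12", "E13", "E14"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180516)
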