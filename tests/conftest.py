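import numpy as np
import pandas as pd
import pytest

from chondrotime.core import ExpressionMatrix, SampleDesign


def make_design(groups: dict[str, int]) -> SampleDesign:
    """Design with the given timepoint -> replicate-count mapping."""
    rows = [
        (f"{tp}_r{r}", tp, r)
        for tp, n in groups.items()
        for r in range(1, n + 1)
    ]
    df = pd.DataFrame(rows, columns=["sample", "timepoint", "replicate"]).set_index("sample")
    return SampleDesign(df)


@pytest.fixture
def two_group_design() -> SampleDesign:
    return make_design({"D0": 3, "D4": 3})


@pytest.fixture
def four_tp_design() -> SampleDesign:
    return make_design({"D0": 3, "D4": 3, "D8": 3, "D12": 3})


@pytest.fixture
def small_matrix(four_tp_design) -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(20)]
    values = pd.DataFrame(
        rng.uniform(1, 100, size=(20, 12)),
        index=genes,
        columns=four_tp_design.sample_ids,
    )
    return ExpressionMatrix(values, four_tp_design)
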