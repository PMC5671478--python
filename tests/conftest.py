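import numpy as np
import pandas as pd
import pytest

from stableref import CqMatrix, ExpressionMatrix, SampleDesign


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 transcripts × 4 samples with known stability behaviour."""
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [2.0, 2.0, 0.0, 100.0],
                "s2": [2.0, 4.0, 5.0, 120.0],
                "s3": [2.0, 3.0, 5.0, 110.0],
                "s4": [2.0, 2.5, 5.0, 105.0],
            },
            index=["flat", "wobbly", "dropout", "high"],
        )
    )


@pytest.fixture
def four_group_design() -> SampleDesign:
    return SampleDesign(
        {"s1": "PI", "s2": "PI", "s3": "PN", "s4": "PN"},
        {"s1": 1, "s2": 2, "s3": 1, "s4": 2},
    )


@pytest.fixture
def abc_cq() -> CqMatrix:
    """Three-gene panel where A and B are parallel and C is noisy."""
    return CqMatrix(
        pd.DataFrame(
            {
                "s1": [20.0, 22.0, 25.0],
                "s2": [21.0, 23.0, 24.0],
                "s3": [20.0, 22.0, 26.0],
                "s4": [21.0, 23.0, 23.0],
            },
            index=["A", "B", "C"],
        )
    )


def random_cq_frame(rng: np.random.Generator, k: int, s: int) -> pd.DataFrame:
    """Random genes × samples Cq grid in a realistic 18–32 cycle window."""
    base = rng.uniform(18, 32, size=(k, 1))
    return pd.DataFrame(
        base + rng.normal(0, 1.0, size=(k, s)),
        index=[f"g{i:02d}" for i in range(k)],
        columns=[f"s{j}" for j in range(s)],
    )
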