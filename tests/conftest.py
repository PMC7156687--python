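import numpy as np
import pytest

from scibet import (
    ExpressionMatrix,
    LabelVector,
    MatrixState,
    SimSpec,
    normalize_umi,
    simulate_counts,
)


@pytest.fixture
def tiny_norm():
    """3 genes × 4 cells, already log-normalized, two cell types."""
    values = np.log1p(
        np.array(
            [
                [5.0, 4.0, 0.0, 1.0],
                [0.0, 1.0, 6.0, 5.0],
                [2.0, 2.0, 2.0, 2.0],
            ]
        )
    )
    m = ExpressionMatrix(
        ["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"], values, MatrixState.NORMALIZED_LOG
    )
    labels = LabelVector(["c1", "c2", "c3", "c4"], ["T", "T", "B", "B"])
    return m, labels


@pytest.fixture(scope="session")
def sim_dataset():
    """One simulated study at the default conditions, shared across tests."""
    raw, labels, markers = simulate_counts(SimSpec(seed=42))
    return normalize_umi(raw), labels, markers
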