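import numpy as np
import pandas as pd
import pytest

from miract.io import ExpressionMatrix, TargetSetCollection
from miract.preprocess import ExpressionChangeVector


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples, two phenotypes, one batch."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(6)]
    values = pd.DataFrame(
        rng.normal(8, 1, (4, 6)),
        index=["G1", "G2", "G3", "G4"],
        columns=samples,
    )
    return ExpressionMatrix(
        values,
        pd.Series("b1", index=samples),
        pd.Series(["case"] * 3 + ["normal"] * 3, index=samples),
    )


def vector_with_ranks(n: int) -> ExpressionChangeVector:
    """Change vector of n genes g00..g(n-1), gene g{i} at rank i."""
    genes = [f"g{i:02d}" for i in range(n)]
    stats = np.arange(n, 0, -1, dtype=float)
    return ExpressionChangeVector(genes, stats, "case", "normal")


@pytest.fixture
def ten_gene_vector() -> ExpressionChangeVector:
    return vector_with_ranks(10)
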