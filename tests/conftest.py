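import numpy as np
import pandas as pd
import pytest

from kdsig import ExpressionMatrix, Signature


@pytest.fixture
def small_expr():
    """3 genes x 4 samples log2 matrix with easily checked statistics."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 6.0, 6.0], [2.0, 4.0, 6.0, 8.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data=data, scale="log2")


@pytest.fixture
def toy_signature():
    return Signature(up=["A"], down=["B"])


def random_expression(rng, n_genes=20, n_samples=6, scale="log2"):
    values = rng.normal(5.0, 1.0, size=(n_genes, n_samples))
    if scale == "linear":
        values = np.abs(values)
    return ExpressionMatrix(
        data=pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        scale=scale,
    )
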