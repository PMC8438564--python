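import numpy as np
import pandas as pd
import pytest

from tmmscope import ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """6 genes x 4 samples, fixed values, includes a tie in s2."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.lognormal(1.0, 1.0, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(4)],
    )
    df.iloc[0, 1] = df.iloc[1, 1]  # tie
    return ExpressionMatrix(df)


@pytest.fixture
def tiny_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet.from_tag("ALT_CHR", ("g0", "g3"), "ALT_CHR"),
            GeneSet.from_tag("Tel_TERT", ("g1", "g4"), "Tel_TERT"),
            GeneSet(name="misc", genes=("g2", "g5", "g0")),
        ]
    )


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int) -> ExpressionMatrix:
    df = pd.DataFrame(
        rng.lognormal(1.0, 1.0, size=(n_genes, n_samples)),
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(df)
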