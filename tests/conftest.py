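from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from duomics.diffexpr import ExpressionMatrix

DATA_DIR = Path(__file__).parent / "data"

BACKGROUND_CARRIERS = 2425
BACKGROUND_GENES = 5586


@pytest.fixture(scope="session")
def group1_fc_pairs() -> pd.DataFrame:
    """Signed fold-change pairs of the 27 published concordantly
    up-regulated (group 1) targets."""
    return pd.read_csv(DATA_DIR / "group1_fc_pairs.tsv", sep="\t", index_col="gene_id")


def make_matrix(values: np.ndarray, feature_ids=None) -> ExpressionMatrix:
    """Wrap a (features x 2k) array as an ExpressionMatrix, first half
    control, second half treated."""
    n = values.shape[1]
    assert n % 2 == 0
    cols = [f"control_{i + 1}" for i in range(n // 2)] + [
        f"treated_{i + 1}" for i in range(n // 2)
    ]
    if feature_ids is None:
        feature_ids = [f"f{i:04d}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=feature_ids, columns=cols)
    return ExpressionMatrix(df, pd.Series({c: c.rsplit("_", 1)[0] for c in cols}))
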