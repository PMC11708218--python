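import numpy as np
import pandas as pd
import pytest

from plkevol.expression import ExpressionTable


@pytest.fixture
def small_table():
    """Two genes, two tissues, female sex, 4 and 2 replicates."""
    cols = pd.MultiIndex.from_tuples(
        [("female", "gonad", 1), ("female", "gonad", 2),
         ("female", "gonad", 3), ("female", "gonad", 4),
         ("female", "head", 1), ("female", "head", 2)],
        names=["sex", "tissue", "replicate"],
    )
    data = np.array(
        [[5.0, 5.0, 5.0, 5.0, 1.0, 2.0],
         [1.0, 2.0, 3.0, 4.0, 0.0, 0.0]]
    )
    return ExpressionTable(
        pd.DataFrame(data, index=pd.Index(["g1", "g2"], name="gene_id"),
                     columns=cols)
    )
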