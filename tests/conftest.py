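import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from rejuvenet.io import CellMatrix


def edge_df(rows):
    """Build an edge DataFrame from (source, target, sign) tuples."""
    return pd.DataFrame(rows, columns=["source", "target", "sign"])


@pytest.fixture
def toy_matrix():
    """3 genes x 4 cells, two cell types, one condition each."""
    counts = sp.csr_matrix(np.array([[2, 0, 4, 1], [1, 1, 0, 0], [0, 3, 2, 5]]))
    meta = pd.DataFrame(
        {
            "cell_type": ["A", "A", "B", "B"],
            "condition": ["treated", "control", "treated", "control"],
            "replicate": ["r1", "r1", "r1", "r1"],
        },
        index=pd.Index(["c1", "c2", "c3", "c4"], name="barcode"),
    )
    return CellMatrix(counts, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"], meta)
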