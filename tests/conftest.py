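import numpy as np
import pandas as pd
import pytest

from serrsig.matrix import ExpressionMatrix


@pytest.fixture
def two_group_matrix():
    """Two groups of two samples with known means and residuals."""
    values = pd.DataFrame(
        {"a1": [0.0, 1.0], "a2": [2.0, 1.0], "b1": [1.0, 3.0], "b2": [3.0, 3.0]},
        index=["g1", "g2"],
    )
    groups = pd.Series({"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
    return ExpressionMatrix(values, groups)


@pytest.fixture
def quartet_matrix():
    """Five-group design, 2 samples/group, deterministic values with noise on one gene."""
    rng = np.random.default_rng(42)
    group_means = {"control": 0.0, "Cdx2KO": 1.0, "BrafVE": 2.0, "Cdx2KO_BrafVE": 5.0, "ApcKO": 3.0}
    cols, labels = [], []
    data = {}
    for g, mu in group_means.items():
        for i in (1, 2):
            sid = f"{g}_{i}"
            cols.append(sid)
            labels.append(g)
            data[sid] = [mu + rng.normal(0, 0.1), mu * 0.5 + rng.normal(0, 0.1)]
    values = pd.DataFrame(data, index=["gA", "gB"])
    return ExpressionMatrix(values, pd.Series(labels, index=cols))
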