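import numpy as np
import pandas as pd
import pytest

from pathcor.io_formats import ExperimentGrouping, GeneSet, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def toy_expression():
    """6 genes x 6 samples, two experiments of 3 samples each."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(1, 7)]
    samples = [f"e1_s{i}" for i in range(1, 4)] + [f"e2_s{i}" for i in range(1, 4)]
    return pd.DataFrame(rng.normal(size=(6, 6)), index=genes, columns=samples)


@pytest.fixture
def toy_grouping(toy_expression):
    return ExperimentGrouping(
        {s: s.split("_")[0] for s in toy_expression.columns}
    )


@pytest.fixture
def toy_collection():
    return GeneSetCollection(
        [
            GeneSet("P1", "first", ("g1", "g2")),
            GeneSet("P2", "second", ("g3", "g4")),
            GeneSet("P3", "third", ("g5", "g6")),
        ]
    )
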