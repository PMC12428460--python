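import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_network():
    """The packaged circCHEK1/circPIM1 worked-example network."""
    from cernaloop.io import load_demo_network

    return load_demo_network()


@pytest.fixture()
def small_dataset():
    """A tiny hand-built expression dataset: 2 genes x 8 samples,
    grade 2 recurrent samples shifted by +2 log2 units in GENE1."""
    from cernaloop.datatypes import ExpressionDataset

    samples = [f"S{i}" for i in range(1, 9)]
    ann = pd.DataFrame(
        {
            "who_grade": [1, 1, 1, 1, 2, 2, 2, 2],
            "recurrent": ["no", "no", "yes", "no", "no", "no", "yes", "yes"],
            "meng_subtype": ["A", "B", None, "A", "B", "C", "C", "C"],
            "chr1p_loss": ["no"] * 8,
            "chr22q_loss": ["no"] * 8,
            "necrosis": [None] * 8,
            "ki67_index": [1.0, 2.0, 3.0, 2.5, 4.0, 5.0, 9.0, 8.0],
        },
        index=samples,
    )
    values = pd.DataFrame(
        {
            "GENE1": [5.0, 5.1, 5.2, 4.9, 6.0, 6.1, 8.0, 8.2],
            "GENE2": [3.0, 3.1, 2.9, 3.2, 3.0, 3.1, 3.05, 2.95],
        },
        index=samples,
    ).T
    return ExpressionDataset(values=values, annotation=ann)
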