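import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_ct_table(rows):
    """Build a long-format Ct table from (sample, kinase, gene, rep, ct) tuples."""
    return pd.DataFrame(
        rows, columns=["sample_id", "kinase_id", "gene_id", "replicate", "ct"]
    )


@pytest.fixture
def simple_ct_table():
    """Two kinases + control, one gene + reference, single replicate.

    CTRL: gene Ct 30, ACTB 20 → rel 2^-10; K1: gene 28 (4-fold up);
    K2: gene 31 (2-fold down).
    """
    return make_ct_table(
        [
            ("S1", "CTRL", "GENEX", 1, 30.0),
            ("S1", "CTRL", "ACTB", 1, 20.0),
            ("S1", "K1", "GENEX", 1, 28.0),
            ("S1", "K1", "ACTB", 1, 20.0),
            ("S1", "K2", "GENEX", 1, 31.0),
            ("S1", "K2", "ACTB", 1, 20.0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20150845)
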