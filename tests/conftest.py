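import numpy as np
import pytest

import thalrisk as tr
from thalrisk import reference


@pytest.fixture(scope="session")
def table3_cohort():
    return reference.load_table3_cohort()


@pytest.fixture(scope="session")
def judgments():
    return reference.load_table7_judgments()


@pytest.fixture(scope="session")
def ahp_weights(judgments):
    weights, report = tr.derive_weights(judgments)
    return weights


@pytest.fixture(scope="session")
def small_cohort():
    """400-record synthetic cohort shared by the heavier tests."""
    return tr.generate(tr.default_spec(n=400, seed=7))


@pytest.fixture(scope="session")
def separable_matrix():
    """Encoded matrix + labels where one feature fully determines the class."""
    rng = np.random.default_rng(11)
    n = 300
    import pandas as pd

    values = pd.DataFrame(
        {
            "signal": np.concatenate([rng.normal(0, 1, n // 2), rng.normal(8, 1, n // 2)]),
            "noise_a": rng.normal(0, 1, n),
            "noise_b": rng.normal(0, 1, n),
        }
    )
    labels = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    matrix = tr.EncodedMatrix(values=values, encoding={c: {"kind": "numeric"} for c in values})
    return matrix, labels
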