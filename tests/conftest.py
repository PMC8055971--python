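import numpy as np
import pytest

from palkit import LabelTable, full_factorial_design


@pytest.fixture(scope="session")
def small_design():
    """2-factor, 2-level DoE with 3 arrangements per composition (12 seqs)."""
    return full_factorial_design([4, 6], n_factors=2, sequences_per_point=3, seed=7)


@pytest.fixture(scope="session")
def toy_gp_data():
    """Small 2-objective training set with one partially labeled candidate."""
    rng = np.random.default_rng(42)
    X = rng.uniform(0.0, 1.0, size=(14, 2))
    labels = LabelTable(2)
    for i in range(14):
        labels.add(i, 0, float(np.sin(3 * X[i, 0]) + X[i, 1]), 0.01)
        if i != 5:  # candidate 5 has objective 1 missing
            labels.add(i, 1, float(np.cos(2 * X[i, 1])), 0.01)
    return X, labels
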