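import numpy as np
import pytest

from tgxddi import ExpressionMatrix, SimulationSpec, simulate_reference_set


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, two per class, hand-pickable numbers."""
    values = np.array(
        [
            [0.0, 2.0, 4.0, 6.0],
            [1.0, 1.5, -1.0, -1.5],
            [0.1, -0.1, 0.2, -0.2],
        ]
    )
    m = ExpressionMatrix(["GA", "GB", "GC"], ["s1", "s2", "s3", "s4"], values)
    labels = ["DDI", "DDI", "NONDDI", "NONDDI"]
    return m, labels


@pytest.fixture(scope="session")
def separated_reference():
    """Well-separated synthetic two-class reference with planted genes."""
    spec = SimulationSpec(
        n_ddi=11, n_nonddi=17, n_genes=500, n_informative=20, effect=3.0, sigma=0.3, seed=42
    )
    matrix, labels, informative = simulate_reference_set(spec)
    return spec, matrix, labels, informative
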