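import numpy as np
import pytest

from shrinklls import ExpressionMatrix, SyntheticSpec, generate, matrix_from_values


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 3 conditions, one missing cell in gene 2."""
    values = np.array(
        [
            [1.0, 2.0, 3.0],
            [2.0, np.nan, 6.0],
            [0.5, 1.0, 1.5],
            [3.0, 2.0, 1.0],
        ]
    )
    return matrix_from_values(values)


@pytest.fixture
def clustered_matrix() -> ExpressionMatrix:
    """100 genes x 8 conditions, 5 clusters, mild noise; complete."""
    return generate(
        SyntheticSpec(
            n_genes=100, n_conditions=8, n_clusters=5,
            within_cluster_noise_sd=0.1, seed=11,
        )
    )


@pytest.fixture
def rank1_matrix() -> ExpressionMatrix:
    """Noiseless single-cluster matrix: every gene a scalar multiple of one
    profile, so local least squares can recover masked entries exactly."""
    return generate(
        SyntheticSpec(
            n_genes=60, n_conditions=8, n_clusters=1,
            within_cluster_noise_sd=0.0, seed=7,
        )
    )
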