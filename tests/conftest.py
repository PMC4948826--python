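import numpy as np
import pytest

from nmfl21 import ExpressionMatrix, SolverConfig, generate_synthetic


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    values = rng.uniform(0.0, 2.0, size=(12, 5))
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(f"g{i}" for i in range(12)),
        sample_ids=tuple(f"s{j}" for j in range(5)),
    )


@pytest.fixture
def planted_instance():
    return generate_synthetic(
        n=200, c=8, d=3, k_outliers=10, outlier_magnitude=5.0, noise_sd=0.05, seed=0
    )


@pytest.fixture
def default_config() -> SolverConfig:
    return SolverConfig(lam=0.3, d=3, seed=0)
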