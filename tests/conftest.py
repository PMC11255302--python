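import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swarmexpr.core_data import (
    ExpressionDataset,
    SyntheticSpec,
    generate_synthetic_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """3 genes × 2 samples, one sample per class."""
    return ExpressionDataset(
        values=np.array([[1.0, 2.0], [3.0, 4.5], [5.25, 6.0]]),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2"],
        labels=["cancer", "normal"],
    )


@pytest.fixture(scope="session")
def small_dataset() -> ExpressionDataset:
    """A fast small synthetic dataset: 120 genes, 20 informative, 15/10 split."""
    return generate_synthetic_dataset(
        SyntheticSpec(
            n_genes=120, n_cancer=15, n_normal=10, n_informative=20,
            effect_size=3.0, block_size=20, seed=7,
        )
    )


@pytest.fixture(scope="session")
def default_dataset() -> ExpressionDataset:
    """The study-shaped default: 2000 genes × 62 samples (40 cancer / 22 normal)."""
    return generate_synthetic_dataset(SyntheticSpec(seed=0))
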