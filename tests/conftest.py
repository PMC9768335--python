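import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ddtg.dream_io import ExpressionPanel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def tiny_panel() -> ExpressionPanel:
    """3-gene worked example used throughout the response-stage tests."""
    return ExpressionPanel(
        gene_names=("G1", "G2", "G3"),
        wild_type=np.array([1.0, 2.0, 3.0]),
        knockout=np.array(
            [
                [0.0, 2.0, 3.0],
                [1.0, 0.0, 6.0],
                [1.0, 4.0, 0.0],
            ]
        ),
    )


@pytest.fixture
def single_edge_panel() -> ExpressionPanel:
    """4 genes, noise-free: deleting G1 halves G2; nothing else responds."""
    wild = np.array([2.0, 4.0, 6.0, 8.0])
    ko = np.tile(wild, (4, 1))
    np.fill_diagonal(ko, 0.0)
    ko[0, 1] = 2.0  # G2 drops when its regulator G1 is removed
    return ExpressionPanel(
        gene_names=("G1", "G2", "G3", "G4"), wild_type=wild, knockout=ko
    )


def random_panel(rng: np.random.Generator, n: int = 6) -> ExpressionPanel:
    """A generic finite panel (no network semantics) for property tests."""
    wild = rng.uniform(1.0, 10.0, size=n)
    ko = np.abs(wild[np.newaxis, :] * (1.0 + rng.normal(0.0, 0.4, size=(n, n))))
    np.fill_diagonal(ko, 0.0)
    return ExpressionPanel(
        gene_names=tuple(f"G{i + 1}" for i in range(n)), wild_type=wild, knockout=ko
    )
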