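import numpy as np
import pytest

from mdboost import AssociationMatrix, SimilarityMatrix, SimulationConfig, generate_dataset


@pytest.fixture
def tiny_assoc() -> AssociationMatrix:
    """2 diseases x 3 microbes worked example used throughout the kernel tests."""
    return AssociationMatrix(
        np.array([[1, 0, 0], [1, 1, 0]]), ["D1", "D2"], ["M1", "M2", "M3"]
    )


@pytest.fixture
def small_dataset():
    """A small planted-block dataset that keeps pipeline tests in seconds."""
    config = SimulationConfig(
        n_diseases=8, n_microbes=16, n_blocks=2, density_in=0.5,
        density_out=0.02, seed=11,
    )
    return generate_dataset(config)


@pytest.fixture
def default_dataset():
    """The generator's default study conditions (20x60, 4 blocks)."""
    return generate_dataset(SimulationConfig(seed=1))


def make_similarity(values, labels, kind="SDM") -> SimilarityMatrix:
    return SimilarityMatrix(np.asarray(values, dtype=float), labels, kind=kind)
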