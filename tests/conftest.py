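import numpy as np
import pytest

from dropal import TabularDataset, generate_bias_fixture
from dropal.oracles import FFTModel, FFTNode


@pytest.fixture(scope="session")
def bias_dataset() -> TabularDataset:
    return generate_bias_fixture(400, seed=1)


@pytest.fixture(scope="session")
def small_bias_dataset() -> TabularDataset:
    return generate_bias_fixture(150, seed=2)


@pytest.fixture
def diabetes_tree() -> FFTModel:
    """Hand-built three-level tree (Insulin -> BMI -> Age) for traversal tests.

    Attribute order: 0 = insulin, 1 = bmi, 2 = age.  High insulin exits
    positive; otherwise high BMI exits positive; age decides the rest.
    """
    return FFTModel(
        nodes=(
            FFTNode(0, 100.0, "above", {"above": 1}),
            FFTNode(1, 30.0, "above", {"above": 1}),
            FFTNode(2, 40.0, "both", {"above": 1, "below": 0}),
        ),
        majority_class=0,
    )


@pytest.fixture
def separable_2d() -> TabularDataset:
    """Tiny noiseless dataset: class 1 iff attribute 0 exceeds its median."""
    rng = np.random.default_rng(7)
    X = rng.uniform(-1, 1, size=(40, 2))
    y = (X[:, 0] > np.median(X[:, 0])).astype(int)
    return TabularDataset(X, y)
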