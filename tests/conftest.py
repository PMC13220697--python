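import numpy as np
import pytest

from fedsplitsim.nn import LayerSpec, ModelSpec, build_reference_model, init_params
from fedsplitsim.synth import GeneratorConfig, PartitionConfig, generate_dataset, split_and_partition


@pytest.fixture(scope="session")
def canonical_spec() -> ModelSpec:
    return build_reference_model()


@pytest.fixture(scope="session")
def tiny_spec() -> ModelSpec:
    """A miniature model covering every layer kind (cheap gradient checks)."""
    return ModelSpec(
        layers=(
            LayerSpec("conv1d", filters=3, kernel=5, padding="same", activation="relu"),
            LayerSpec("maxpool1d", pool=2),
            LayerSpec("conv1d", filters=4, kernel=3, padding="valid", activation="relu"),
            LayerSpec("flatten"),
            LayerSpec("dense", units=5, activation="relu"),
            LayerSpec("dense", units=2),
            LayerSpec("softmax"),
        ),
        input_length=21,
        input_channels=1,
        cut_layer=4,
    )


@pytest.fixture(scope="session")
def tiny_batch(tiny_spec):
    rng = np.random.default_rng(11)
    X = rng.normal(size=(6, tiny_spec.input_length))
    y = rng.integers(0, 2, size=6)
    return X, y


@pytest.fixture(scope="session")
def small_dataset():
    """10 users x 100 segments, default morphology/noise."""
    return generate_dataset(GeneratorConfig(n_users=10, segments_per_user=100, seed=7))


@pytest.fixture(scope="session")
def small_partition(small_dataset):
    pc = PartitionConfig(n_clients=4, test_fraction=0.2, dirichlet_alpha=0.5, seed=3)
    return split_and_partition(small_dataset, pc)
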