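import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fragvec import (
    AnalogueSeries,
    EmbeddingConfig,
    Fragment,
    train_embedding,
)
from fragvec.synthetic import SyntheticSpec, generate_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Small planted-cluster corpus spec for fast unit tests."""
    return SyntheticSpec(
        n_clusters=4,
        fragments_per_cluster=10,
        n_series=60,
        series_length_range=(5, 8),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return generate_corpus(small_spec)


@pytest.fixture(scope="session")
def fixture_model(small_corpus):
    """A deterministic low-dimensional model over the small corpus."""
    config = EmbeddingConfig(vector_size=32, epochs=40, seed=3)
    return train_embedding(small_corpus, config)


@pytest.fixture()
def example_series() -> AnalogueSeries:
    """An 11-member series with distinct pIC50 values, the shape of the
    worked weighted-query example (10 non-terminal members)."""
    smiles = [
        "[*]C", "[*]CC", "[*]CCC", "[*]O", "[*]OC", "[*]N", "[*]F",
        "[*]Cl", "[*]Br", "[*]C#N", "[*]c1ccccc1",
    ]
    rng = np.random.default_rng(42)
    potencies = np.sort(5.0 + 4.0 * rng.random(11))
    members = [
        (Fragment.from_smiles(s), float(p)) for s, p in zip(smiles, potencies)
    ]
    return AnalogueSeries("fixture-11", members)
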