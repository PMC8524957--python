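import numpy as np
import pytest

from ubisent.corpus import E3Dictionary
from ubisent.representation import RepresentationBuilder, expand_instances
from ubisent.synthetic import GeneratorConfig, default_fixture, generate_corpus


@pytest.fixture(scope="session")
def fixture_dictionary() -> E3Dictionary:
    dictionary, _ = default_fixture()
    return dictionary


@pytest.fixture(scope="session")
def fixture_substrates() -> tuple[str, ...]:
    _, substrates = default_fixture()
    return substrates


@pytest.fixture(scope="session")
def small_corpus(fixture_dictionary, fixture_substrates):
    """60 positives + 120 negatives, clean labels, fixed seed."""
    config = GeneratorConfig(
        n_positive=60,
        n_negative=120,
        e3_dict=fixture_dictionary,
        substrate_names=fixture_substrates,
        seed=42,
    )
    return generate_corpus(config)


@pytest.fixture(scope="session")
def small_features(small_corpus):
    """Low-width features of the small corpus: (X, y), 5 x 8 = 40 dims."""
    instances, y = expand_instances(small_corpus)
    builder = RepresentationBuilder(channel_dim=8)
    X = builder.fit(instances).transform(instances)
    return X, y
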