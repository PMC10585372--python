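import pytest

from morphotax.fixtures import (
    load_nereididae_genera, load_printed_diagnoses, load_printed_key,
)
from morphotax.keys import Key
from morphotax.model import Attribute, CharacterDefinition, Dataset, TaxonRecord
from morphotax.synthetic import SyntheticParams, generate_synthetic


@pytest.fixture(scope="session")
def nereid():
    return load_nereididae_genera()


@pytest.fixture(scope="session")
def printed_key():
    return Key.from_json(load_printed_key())


@pytest.fixture(scope="session")
def printed_diagnoses():
    return load_printed_diagnoses()


@pytest.fixture
def tiny_dataset():
    """Two taxa, three characters: one separating binary, one shared, one
    numeric."""
    chars = [
        CharacterDefinition(number=1, label="crest", states=("present", "absent")),
        CharacterDefinition(number=2, label="colour", states=("red", "blue")),
        CharacterDefinition(number=3, label="spine count", kind="numeric",
                            unit="count"),
    ]
    taxa = [
        TaxonRecord("Alpha", "A, 1900", {
            1: Attribute.recorded({1}),
            2: Attribute.recorded({1}),
            3: Attribute.numeric(2, 4),
        }),
        TaxonRecord("Beta", "B, 1901", {
            1: Attribute.recorded({2}),
            2: Attribute.recorded({1}),
            3: Attribute.numeric(5, 7),
        }),
    ]
    return Dataset(characters=chars, taxa=taxa, title="tiny")


def synth(seed, n_taxa=8, n_characters=10, **kw):
    kw.setdefault("polymorphism_rate", 0.15)
    kw.setdefault("unknown_rate", 0.1)
    return generate_synthetic(SyntheticParams(
        n_taxa=n_taxa, n_characters=n_characters, seed=seed, **kw))
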