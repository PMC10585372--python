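import pytest
from hypothesis import given, settings, strategies as st

from morphotax.model import (
    Attribute, AttributeStatus, CharacterDefinition, Dataset, Dependency,
    LookupError_, TaxonRecord, attributes_differ, differ,
    distinguishing_characters, validate_dataset,
)

from conftest import synth


# ---------------------------------------------------------------------------
# Attribute / CharacterDefinition invariants
# ---------------------------------------------------------------------------

def test_attribute_payload_exclusive():
    with pytest.raises(ValueError):
        Attribute(AttributeStatus.RECORDED)  # no payload
    with pytest.raises(ValueError):
        Attribute(AttributeStatus.RECORDED, frozenset({1}), (1.0, 2.0))
    with pytest.raises(ValueError):
        Attribute(AttributeStatus.UNKNOWN, frozenset({1}))
    with pytest.raises(ValueError):
        Attribute.numeric(5, 3)


def test_polymorphism_flag():
    assert Attribute.recorded({1, 2}).is_polymorphic
    assert not Attribute.recorded({2}).is_polymorphic


def test_character_invariants():
    with pytest.raises(ValueError):
        CharacterDefinition(number=1, label="x", states=("only",))
    with pytest.raises(ValueError):
        CharacterDefinition(number=0, label="x", states=("a", "b"))
    with pytest.raises(ValueError):
        CharacterDefinition(number=1, label="x", kind="numeric",
                            states=("a", "b"))
    with pytest.raises(ValueError):
        CharacterDefinition(number=1, label="x", states=("a", "b"),
                            reliability=11)


# ---------------------------------------------------------------------------
# differ
# ---------------------------------------------------------------------------

def test_differ_published_example_oral_ring_paragnaths(nereid):
    # Hediste has oral ring paragnaths, Simplisetia lacks them
    assert differ(nereid, "Hediste", "Simplisetia", 55) is True


def test_differ_identity_is_false(nereid):
    for name in nereid.taxon_names[:10]:
        assert differ(nereid, name, name, 55) is False


def test_differ_polymorphic_overlap_is_false(nereid):
    # Eunereis is recorded "present, or absent" for oral ring papillae, so it
    # can never provably differ from Websterinereis (papillae present)
    assert nereid.attribute("Eunereis", 45).states == frozenset({1, 2})
    assert differ(nereid, "Eunereis", "Websterinereis", 45) is False


def test_differ_unknown_never_differs(tiny_dataset):
    tiny_dataset.taxon("Alpha").attributes[1] = Attribute.unknown()
    assert differ(tiny_dataset, "Alpha", "Beta", 1) is False


def test_differ_numeric_interval_overlap(tiny_dataset):
    assert differ(tiny_dataset, "Alpha", "Beta", 3) is True  # [2,4] vs [5,7]
    tiny_dataset.taxon("Beta").attributes[3] = Attribute.numeric(4, 7)
    assert differ(tiny_dataset, "Alpha", "Beta", 3) is False  # touch at 4


def test_differ_unknown_names_raise(tiny_dataset):
    with pytest.raises(LookupError_):
        differ(tiny_dataset, "Alpha", "Nope", 1)
    with pytest.raises(LookupError_):
        differ(tiny_dataset, "Alpha", "Beta", 99)


# ---------------------------------------------------------------------------
# distinguishing_characters
# ---------------------------------------------------------------------------

def test_distinguishing_published_example(nereid):
    # Nectoneanthes has sesquigomph notochaetal spinigers, Alitta lacks them
    assert 133 in distinguishing_characters(nereid, "Alitta", "Nectoneanthes")


def test_distinguishing_self_empty(nereid):
    assert distinguishing_characters(nereid, "Nereis", "Nereis") == []


def _oracle_distinguishing(dataset, a, b):
    """Independent brute-force: re-derive differences from raw payloads."""
    out = []
    ta, tb = dataset.taxon(a), dataset.taxon(b)
    for char in dataset.characters:
        x = ta.attributes.get(char.number)
        y = tb.attributes.get(char.number)
        if x is None or y is None:
            continue
        if x.status.value != "recorded" or y.status.value != "recorded":
            continue
        if x.states and y.states:
            if len(x.states | y.states) == len(x.states) + len(y.states):
                out.append(char.number)
        elif x.range and y.range:
            if x.range[1] < y.range[0] or y.range[1] < x.range[0]:
                out.append(char.number)
    return out


@pytest.mark.parametrize("seed", range(100))
def test_distinguishing_matches_bruteforce_on_synthetic(seed):
    ds = synth(seed, n_taxa=5, n_characters=8, numeric_fraction=0.25)
    names = ds.taxon_names
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            got = distinguishing_characters(ds, a, b)
            assert got == _oracle_distinguishing(ds, a, b)
            assert got == distinguishing_characters(ds, b, a)  # symmetry


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

attr_strategy = st.one_of(
    st.just(Attribute.unknown()),
    st.just(Attribute.inapplicable()),
    st.sets(st.integers(1, 4), min_size=1, max_size=4).map(Attribute.recorded),
    st.tuples(st.integers(0, 10), st.integers(0, 10)).map(
        lambda lohi: Attribute.numeric(min(lohi), max(lohi))),
)


@given(attr_strategy, attr_strategy)
@settings(max_examples=200, deadline=None)
def test_attributes_differ_symmetric_irreflexive(a, b):
    assert attributes_differ(a, b) == attributes_differ(b, a)
    assert attributes_differ(a, a) is False
    if not (a.is_recorded and b.is_recorded):
        assert attributes_differ(a, b) is False


# ---------------------------------------------------------------------------
# validate_dataset
# ---------------------------------------------------------------------------

def test_validate_fixture_clean(nereid):
    report = validate_dataset(nereid)
    assert report.ok
    assert report.n_taxa == 45
    assert report.n_multistate == 146
    assert report.n_numeric == 40


def test_validate_bad_state_code(tiny_dataset):
    tiny_dataset.taxon("Alpha").attributes[1] = Attribute.recorded({4})
    report = validate_dataset(tiny_dataset)
    assert [i.kind for i in report.issues] == ["bad-state"]


def test_validate_dependency_violation():
    chars = [
        CharacterDefinition(number=5, label="palpostyles",
                            states=("present", "absent (palps undivided)")),
        CharacterDefinition(number=6, label="palpostyle form",
                            states=("spherical", "conical"),
                            dependencies=(Dependency(5, frozenset({1})),)),
    ]
    taxa = [TaxonRecord("X", attributes={
        5: Attribute.recorded({2}),
        6: Attribute.recorded({1}),  # recorded although palpostyles absent
    })]
    report = validate_dataset(Dataset(chars, taxa))
    assert any(i.kind == "dependency-violation" and i.character == 6
               for i in report.issues)


def test_validate_duplicate_names():
    chars = [CharacterDefinition(number=1, label="c", states=("a", "b"))]
    taxa = [TaxonRecord("X"), TaxonRecord("X")]
    report = validate_dataset(Dataset(chars, taxa))
    assert any(i.kind == "duplicate-taxon" for i in report.issues)


def test_validate_dependency_cycle():
    chars = [
        CharacterDefinition(number=1, label="a", states=("x", "y"),
                            dependencies=(Dependency(2, frozenset({1})),)),
        CharacterDefinition(number=2, label="b", states=("x", "y"),
                            dependencies=(Dependency(1, frozenset({1})),)),
    ]
    report = validate_dataset(Dataset(chars, []))
    assert any(i.kind == "dependency-cycle" for i in report.issues)


def test_partition_sums(nereid):
    report = validate_dataset(nereid)
    assert report.n_multistate + report.n_numeric == len(nereid.characters) == 186
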