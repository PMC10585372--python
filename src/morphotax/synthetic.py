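"""Seeded synthetic dataset generation for testing and benchmarking.

Emulates the structure of real morphological matrices: unordered multistate
characters with 2-5 states, numeric (meristic) characters, controlled rates
of polymorphism and unknown cells, and optional applicability dependencies.
Generation is a pure function of :class:`SyntheticParams` (same seed, same
dataset, byte for byte).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    Attribute, CharacterDefinition, CharacterKind, Dataset, Dependency,
    TaxonRecord, distinguishing_characters,
)

__all__ = ["SyntheticParams", "GenerationError", "generate_synthetic"]


class GenerationError(RuntimeError):
    """Requested guarantees could not be met."""


@dataclass(frozen=True)
class SyntheticParams:
    n_taxa: int
    n_characters: int
    seed: int
    numeric_fraction: float = 0.0
    states_distribution: tuple[int, ...] = (2, 2, 2, 3, 4, 5)
    polymorphism_rate: float = 0.0
    unknown_rate: float = 0.0
    dependency_rate: float = 0.0
    guarantee_distinct: bool = False
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_characters < 1:
            raise ValueError("need at least one taxon and one character")
        for name in ("numeric_fraction", "polymorphism_rate", "unknown_rate",
                     "dependency_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(not 2 <= s <= 5 for s in self.states_distribution):
            raise ValueError("multistate characters must have 2-5 states")


def generate_synthetic(params: SyntheticParams) -> Dataset:
    """Generate a random dataset matching ``params``.

    With ``guarantee_distinct`` every taxon pair differs (provably, per the
    disjointness comparison) on at least one character; the matrix is
    resampled up to ``max_retries`` times until that holds.
    """
    rng = random.Random(params.seed)
    for attempt in range(params.max_retries):
        dataset = _generate_once(params, rng)
        if not params.guarantee_distinct:
            return dataset
        if _all_distinct(dataset):
            return dataset
    raise GenerationError(
        f"could not generate {params.n_taxa} pairwise-distinguishable taxa on "
        f"{params.n_characters} characters after {params.max_retries} attempts")


def _generate_once(params: SyntheticParams, rng: random.Random) -> Dataset:
    n_numeric = round(params.n_characters * params.numeric_fraction)
    numeric_numbers = set(rng.sample(range(1, params.n_characters + 1),
                                     n_numeric)) if n_numeric else set()

    characters: list[CharacterDefinition] = []
    for num in range(1, params.n_characters + 1):
        if num in numeric_numbers:
            characters.append(CharacterDefinition(
                number=num, label=f"character {num} (count)",
                kind=CharacterKind.NUMERIC, unit="count"))
            continue
        k = rng.choice(params.states_distribution)
        deps: tuple[Dependency, ...] = ()
        if num > 1 and rng.random() < params.dependency_rate:
            # depend on an earlier multistate character's state 1
            earlier = [c for c in characters
                       if c.kind is CharacterKind.MULTISTATE]
            if earlier:
                ctrl = rng.choice(earlier)
                deps = (Dependency(ctrl.number, frozenset({1})),)
        characters.append(CharacterDefinition(
            number=num, label=f"character {num}",
            states=tuple(f"state {i}" for i in range(1, k + 1)),
            dependencies=deps))
    char_by_num = {c.number: c for c in characters}

    taxa: list[TaxonRecord] = []
    for t in range(1, params.n_taxa + 1):
        attrs: dict[int, Attribute] = {}
        for c in characters:
            # dependency-aware: controller recorded outside enabling states
            # forces INAPPLICABLE
            inapplicable = False
            for dep in c.dependencies:
                ctrl_attr = attrs.get(dep.controller)
                if ctrl_attr is not None and ctrl_attr.is_recorded \
                        and ctrl_attr.states and not ctrl_attr.states & dep.states:
                    inapplicable = True
            if inapplicable:
                attrs[c.number] = Attribute.inapplicable()
                continue
            if rng.random() < params.unknown_rate:
                attrs[c.number] = Attribute.unknown()
                continue
            if c.kind is CharacterKind.NUMERIC:
                lo = rng.randint(0, 30)
                hi = lo + (rng.randint(1, 10) if rng.random() < 0.5 else 0)
                attrs[c.number] = Attribute.numeric(lo, hi)
            else:
                k = c.n_states
                if k > 1 and rng.random() < params.polymorphism_rate:
                    size = rng.randint(2, k)
                    states = rng.sample(range(1, k + 1), size)
                else:
                    states = [rng.randint(1, k)]
                attrs[c.number] = Attribute.recorded(states)
        taxa.append(TaxonRecord(name=f"Taxon_{t:03d}", authority="Synth, 2024",
                                attributes=attrs))

    return Dataset(characters=characters, taxa=taxa,
                   title=f"synthetic seed={params.seed}")


def _all_distinct(dataset: Dataset) -> bool:
    names = dataset.taxon_names
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if not distinguishing_characters(dataset, a, b):
                return False
    return True
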