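"""Core domain model: characters, attributes, taxa, datasets.

All character numbers and state codes are 1-based; nothing user-visible is
ever 0-based.  A matrix cell (:class:`Attribute`) is either RECORDED (with a
state set or a numeric interval), UNKNOWN, or INAPPLICABLE.  The comparison
semantics used by every downstream algorithm live here: two taxa *differ* on
a character only when both sides are RECORDED and their payloads are
disjoint.  UNKNOWN and INAPPLICABLE never create a difference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CharacterKind",
    "AttributeStatus",
    "CharacterDefinition",
    "Attribute",
    "TaxonRecord",
    "Dataset",
    "ValidationIssue",
    "ValidationReport",
    "LookupError_",
    "differ",
    "attributes_differ",
    "distinguishing_characters",
    "validate_dataset",
]


class CharacterKind(str, enum.Enum):
    MULTISTATE = "multistate"
    NUMERIC = "numeric"


class AttributeStatus(str, enum.Enum):
    RECORDED = "recorded"
    UNKNOWN = "unknown"
    INAPPLICABLE = "inapplicable"


class LookupError_(KeyError):
    """Unknown taxon or character referenced by name/number."""


@dataclass(frozen=True)
class Dependency:
    """This character is applicable only when the controlling character is
    RECORDED with at least one of ``states``."""

    controller: int
    states: frozenset[int]

    def to_json(self) -> dict:
        return {"controller": self.controller, "states": sorted(self.states)}

    @classmethod
    def from_json(cls, obj: Mapping) -> "Dependency":
        return cls(int(obj["controller"]), frozenset(int(s) for s in obj["states"]))


@dataclass(frozen=True)
class CharacterDefinition:
    number: int
    label: str
    kind: CharacterKind = CharacterKind.MULTISTATE
    states: tuple[str, ...] = ()
    unit: str = ""
    reliability: float = 5.0
    dependencies: tuple[Dependency, ...] = ()
    section: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CharacterKind(self.kind))
        object.__setattr__(self, "states", tuple(self.states))
        if self.number < 1:
            raise ValueError(f"character number must be >= 1, got {self.number}")
        if self.kind is CharacterKind.MULTISTATE and len(self.states) < 2:
            raise ValueError(
                f"multistate character {self.number} needs >= 2 states, "
                f"got {len(self.states)}"
            )
        if self.kind is CharacterKind.NUMERIC and self.states:
            raise ValueError(f"numeric character {self.number} must not declare states")
        if not 0.0 <= self.reliability <= 10.0:
            raise ValueError("reliability must lie in [0, 10]")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_label(self, code: int) -> str:
        if not 1 <= code <= len(self.states):
            raise LookupError_(f"character {self.number} has no state {code}")
        return self.states[code - 1]

    def to_json(self) -> dict:
        obj: dict = {"number": self.number, "label": self.label, "kind": self.kind.value}
        if self.states:
            obj["states"] = list(self.states)
        if self.unit:
            obj["unit"] = self.unit
        if self.reliability != 5.0:
            obj["reliability"] = self.reliability
        if self.dependencies:
            obj["dependencies"] = [d.to_json() for d in self.dependencies]
        if self.section:
            obj["section"] = self.section
        return obj

    @classmethod
    def from_json(cls, obj: Mapping) -> "CharacterDefinition":
        return cls(
            number=int(obj["number"]),
            label=str(obj["label"]),
            kind=CharacterKind(obj.get("kind", "multistate")),
            states=tuple(obj.get("states", ())),
            unit=str(obj.get("unit", "")),
            reliability=float(obj.get("reliability", 5.0)),
            dependencies=tuple(
                Dependency.from_json(d) for d in obj.get("dependencies", ())
            ),
            section=str(obj.get("section", "")),
        )


@dataclass(frozen=True)
class Attribute:
    """One matrix cell.

    Exactly one payload is meaningful for a RECORDED cell: ``states`` for a
    multistate character, ``range`` (closed interval, lo <= hi) for a numeric
    one.  ``comment`` carries free text verbatim.
    """

    status: AttributeStatus = AttributeStatus.UNKNOWN
    states: frozenset[int] = frozenset()
    range: tuple[float, float] | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", AttributeStatus(self.status))
        object.__setattr__(self, "states", frozenset(self.states))
        if self.status is AttributeStatus.RECORDED:
            if bool(self.states) == (self.range is not None):
                raise ValueError("RECORDED attribute needs exactly one payload")
            if self.range is not None and self.range[0] > self.range[1]:
                raise ValueError(f"numeric range reversed: {self.range}")
        elif self.states or self.range is not None:
            raise ValueError(f"{self.status.value} attribute must carry no payload")

    # -- constructors ------------------------------------------------------
    @classmethod
    def recorded(cls, states: Iterable[int], comment: str = "") -> "Attribute":
        return cls(AttributeStatus.RECORDED, frozenset(states), None, comment)

    @classmethod
    def numeric(cls, lo: float, hi: float | None = None, comment: str = "") -> "Attribute":
        hi = lo if hi is None else hi
        return cls(AttributeStatus.RECORDED, frozenset(), (float(lo), float(hi)), comment)

    @classmethod
    def unknown(cls, comment: str = "") -> "Attribute":
        return cls(AttributeStatus.UNKNOWN, frozenset(), None, comment)

    @classmethod
    def inapplicable(cls, comment: str = "") -> "Attribute":
        return cls(AttributeStatus.INAPPLICABLE, frozenset(), None, comment)

    # -- predicates --------------------------------------------------------
    @property
    def is_recorded(self) -> bool:
        return self.status is AttributeStatus.RECORDED

    @property
    def is_polymorphic(self) -> bool:
        return len(self.states) >= 2

    def to_json(self) -> dict:
        obj: dict = {}
        if self.status is AttributeStatus.RECORDED:
            if self.states:
                obj["states"] = sorted(self.states)
            else:
                obj["range"] = list(self.range)  # type: ignore[arg-type]
        else:
            obj["status"] = self.status.value
        if self.comment:
            obj["comment"] = self.comment
        return obj

    @classmethod
    def from_json(cls, obj: Mapping) -> "Attribute":
        comment = str(obj.get("comment", ""))
        if "states" in obj:
            return cls.recorded((int(s) for s in obj["states"]), comment)
        if "range" in obj:
            lo, hi = obj["range"]
            return cls.numeric(float(lo), float(hi), comment)
        status = AttributeStatus(obj.get("status", "unknown"))
        return cls(status, frozenset(), None, comment)


@dataclass
class TaxonRecord:
    name: str
    authority: str = ""
    attributes: dict[int, Attribute] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def attribute(self, number: int) -> Attribute:
        return self.attributes.get(number, Attribute.unknown())

    def to_json(self) -> dict:
        obj: dict = {"name": self.name}
        if self.authority:
            obj["authority"] = self.authority
        obj["attributes"] = {
            str(c): self.attributes[c].to_json() for c in sorted(self.attributes)
        }
        if self.metadata:
            obj["metadata"] = dict(sorted(self.metadata.items()))
        return obj

    @classmethod
    def from_json(cls, obj: Mapping) -> "TaxonRecord":
        return cls(
            name=str(obj["name"]),
            authority=str(obj.get("authority", "")),
            attributes={
                int(c): Attribute.from_json(a)
                for c, a in obj.get("attributes", {}).items()
            },
            metadata=dict(obj.get("metadata", {})),
        )


@dataclass
class Dataset:
    """A character list plus taxon records; the unit every algorithm consumes."""

    characters: list[CharacterDefinition]
    taxa: list[TaxonRecord]
    title: str = ""

    def __post_init__(self) -> None:
        self._char_index = {c.number: c for c in self.characters}
        self._taxon_index = {t.name: t for t in self.taxa}

    def reindex(self) -> None:
        self.__post_init__()

    # -- lookups -----------------------------------------------------------
    def character(self, number: int) -> CharacterDefinition:
        try:
            return self._char_index[number]
        except KeyError:
            raise LookupError_(f"no character numbered {number}") from None

    def taxon(self, name: str) -> TaxonRecord:
        try:
            return self._taxon_index[name]
        except KeyError:
            raise LookupError_(f"no taxon named {name!r}") from None

    def has_taxon(self, name: str) -> bool:
        return name in self._taxon_index

    def has_character(self, number: int) -> bool:
        return number in self._char_index

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    @property
    def character_numbers(self) -> list[int]:
        return [c.number for c in self.characters]

    def multistate_characters(self) -> list[CharacterDefinition]:
        return [c for c in self.characters if c.kind is CharacterKind.MULTISTATE]

    def numeric_characters(self) -> list[CharacterDefinition]:
        return [c for c in self.characters if c.kind is CharacterKind.NUMERIC]

    def attribute(self, taxon: str, number: int) -> Attribute:
        return self.taxon(taxon).attribute(number)

    # -- serialization -----------------------------------------------------
    SCHEMA_VERSION = "1"

    def to_json(self) -> dict:
        return {
            "format": "morphotax-dataset",
            "version": self.SCHEMA_VERSION,
            "title": self.title,
            "characters": [c.to_json() for c in self.characters],
            "taxa": [t.to_json() for t in self.taxa],
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "Dataset":
        if obj.get("format", "morphotax-dataset") != "morphotax-dataset":
            raise ValueError(f"not a morphotax dataset: format={obj.get('format')!r}")
        return cls(
            characters=[CharacterDefinition.from_json(c) for c in obj["characters"]],
            taxa=[TaxonRecord.from_json(t) for t in obj["taxa"]],
            title=str(obj.get("title", "")),
        )

    def copy(self) -> "Dataset":
        return Dataset.from_json(self.to_json())


# ---------------------------------------------------------------------------
# Comparison semantics
# ---------------------------------------------------------------------------

def attributes_differ(a: Attribute, b: Attribute) -> bool:
    """True iff both cells are RECORDED and their payloads are disjoint."""
    if not (a.is_recorded and b.is_recorded):
        return False
    if a.states and b.states:
        return not (a.states & b.states)
    if a.range is not None and b.range is not None:
        return a.range[1] < b.range[0] or b.range[1] < a.range[0]
    return False  # mixed payloads cannot be compared


def differ(dataset: Dataset, a: str, b: str, c: int) -> bool:
    """Do taxa ``a`` and ``b`` provably differ on character ``c``?

    Symmetric; never true when either side is UNKNOWN or INAPPLICABLE.
    """
    dataset.character(c)  # raise on bad character number
    return attributes_differ(dataset.taxon(a).attribute(c), dataset.taxon(b).attribute(c))


def distinguishing_characters(dataset: Dataset, a: str, b: str) -> list[int]:
    """All characters on which ``a`` and ``b`` differ, ascending."""
    ta, tb = dataset.taxon(a), dataset.taxon(b)
    return [
        c.number
        for c in dataset.characters
        if attributes_differ(ta.attribute(c.number), tb.attribute(c.number))
    ]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    taxon: str
    character: int
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]
    n_taxa: int
    n_multistate: int
    n_numeric: int

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def n_characters(self) -> int:
        return self.n_multistate + self.n_numeric

    def summary(self) -> str:
        head = (
            f"{self.n_taxa} taxa, {self.n_characters} characters "
            f"({self.n_multistate} multistate, {self.n_numeric} numeric)"
        )
        if self.ok:
            return head + "; no violations"
        return head + f"; {len(self.issues)} violation(s)"


def _dependency_excludes(dataset: Dataset, taxon: TaxonRecord, char: CharacterDefinition) -> Dependency | None:
    """Return the violated dependency if ``char`` is provably inapplicable for
    ``taxon`` (controller RECORDED entirely outside the enabling states)."""
    for dep in char.dependencies:
        ctrl = taxon.attribute(dep.controller)
        if ctrl.is_recorded and ctrl.states and not (ctrl.states & dep.states):
            return dep
    return None


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Report-based validation: never raises, lists every violation found."""
    issues: list[ValidationIssue] = []

    seen_chars: set[int] = set()
    for char in dataset.characters:
        if char.number in seen_chars:
            issues.append(ValidationIssue(
                "duplicate-character", "", char.number,
                f"character number {char.number} declared more than once"))
        seen_chars.add(char.number)
        for dep in char.dependencies:
            if dep.controller not in dataset._char_index:
                issues.append(ValidationIssue(
                    "bad-dependency", "", char.number,
                    f"dependency on undeclared character {dep.controller}"))

    # dependency graph must be acyclic
    graph = {c.number: [d.controller for d in c.dependencies] for c in dataset.characters}
    state: dict[int, int] = {}

    def visit(n: int) -> bool:  # True when a cycle is found
        state[n] = 1
        for m in graph.get(n, ()):
            s = state.get(m, 0)
            if s == 1 or (s == 0 and visit(m)):
                return True
        state[n] = 2
        return False

    for n in graph:
        if state.get(n, 0) == 0 and visit(n):
            issues.append(ValidationIssue(
                "dependency-cycle", "", n, f"dependency cycle through character {n}"))
            break

    seen_taxa: set[str] = set()
    for taxon in dataset.taxa:
        if taxon.name in seen_taxa:
            issues.append(ValidationIssue(
                "duplicate-taxon", taxon.name, 0,
                f"taxon {taxon.name!r} declared more than once"))
        seen_taxa.add(taxon.name)

        for number, attr in taxon.attributes.items():
            if number not in dataset._char_index:
                issues.append(ValidationIssue(
                    "unknown-character", taxon.name, number,
                    f"attribute references undeclared character {number}"))
                continue
            char = dataset.character(number)
            if attr.is_recorded:
                if char.kind is CharacterKind.MULTISTATE:
                    if not attr.states:
                        issues.append(ValidationIssue(
                            "payload-mismatch", taxon.name, number,
                            "numeric payload on a multistate character"))
                    else:
                        bad = [s for s in attr.states if not 1 <= s <= char.n_states]
                        if bad:
                            issues.append(ValidationIssue(
                                "bad-state", taxon.name, number,
                                f"state code(s) {sorted(bad)} outside 1..{char.n_states}"))
                elif attr.range is None:
                    issues.append(ValidationIssue(
                        "payload-mismatch", taxon.name, number,
                        "state-set payload on a numeric character"))
                dep = _dependency_excludes(dataset, taxon, char)
                if dep is not None:
                    issues.append(ValidationIssue(
                        "dependency-violation", taxon.name, number,
                        f"recorded although controller {dep.controller} excludes "
                        f"applicability (enabling states {sorted(dep.states)})"))

    return ValidationReport(
        issues=issues,
        n_taxa=len(dataset.taxa),
        n_multistate=sum(1 for c in dataset.characters if c.kind is CharacterKind.MULTISTATE),
        n_numeric=sum(1 for c in dataset.characters if c.kind is CharacterKind.NUMERIC),
    )
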