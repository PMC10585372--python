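"""Interactive multi-entry identification with error tolerance.

Rather than hard elimination, each taxon accumulates a mismatch count (a
mismatch is a recorded taxon attribute disjoint from the asserted specimen
observation); candidates are the taxa with at most ``tolerance`` mismatches.
UNKNOWN or INAPPLICABLE taxon data never mismatches, so taxa are never
eliminated on unscored cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .model import (
    Attribute, AttributeStatus, CharacterKind, Dataset, attributes_differ,
)

__all__ = ["IdentificationSession", "differences_report"]


@dataclass
class IdentificationSession:
    dataset: Dataset
    tolerance: int = 0
    asserted: dict[int, Attribute] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    # -- state -------------------------------------------------------------
    def mismatch_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.dataset.taxa:
            counts[t.name] = sum(
                1 for c, obs in self.asserted.items()
                if attributes_differ(t.attribute(c), obs))
        return counts

    def candidates(self) -> list[str]:
        counts = self.mismatch_counts()
        return [t.name for t in self.dataset.taxa
                if counts[t.name] <= self.tolerance]

    # -- operations --------------------------------------------------------
    def assert_attribute(self, c: int, observed) -> "IdentificationSession":
        """Record an observation; re-asserting a character replaces the prior
        assertion.  ``observed`` is a state code, an iterable of codes, a
        number, a (lo, hi) pair, or an :class:`Attribute`."""
        char = self.dataset.character(c)
        attr = _coerce(observed, char)
        if char.kind is CharacterKind.MULTISTATE and attr.states:
            bad = [s for s in attr.states if not 1 <= s <= char.n_states]
            if bad:
                raise ValueError(
                    f"state code(s) {sorted(bad)} outside 1..{char.n_states} "
                    f"for character {c}")
        self.asserted[c] = attr
        return self

    def retract(self, c: int) -> "IdentificationSession":
        self.asserted.pop(c, None)
        return self

    def rank_characters(self) -> list[tuple[int, float]]:
        """Unasserted usable characters ranked by expected remaining
        candidates (ascending; lower separates better), under a uniform
        prior over the candidates' recorded states.  Empty when fewer than
        two candidates remain."""
        cands = self.candidates()
        if len(cands) < 2:
            return []
        ranked: list[tuple[float, int]] = []
        for char in self.dataset.multistate_characters():
            c = char.number
            if c in self.asserted:
                continue
            states = sorted({
                s for t in cands
                for s in self.dataset.attribute(t, c).states})
            if not states:
                continue  # unknown for every candidate: unusable
            expected = _expected_remaining(self.dataset, cands, c, states,
                                           self.tolerance,
                                           self.mismatch_counts())
            ranked.append((expected, c))
        ranked.sort(key=lambda ec: (ec[0], ec[1]))
        return [(c, e) for e, c in ranked]


def _expected_remaining(dataset: Dataset, cands: list[str], c: int,
                        states: list[int], tolerance: int,
                        counts: Mapping[str, int]) -> float:
    total = 0.0
    for s in states:
        obs = Attribute.recorded({s})
        remaining = sum(
            1 for t in cands
            if counts[t] + (1 if attributes_differ(
                dataset.attribute(t, c), obs) else 0) <= tolerance)
        total += remaining
    return total / len(states)


def _coerce(observed, char) -> Attribute:
    if isinstance(observed, Attribute):
        return observed
    if char.kind is CharacterKind.NUMERIC:
        if isinstance(observed, (tuple, list)):
            lo, hi = observed
            return Attribute.numeric(float(lo), float(hi))
        return Attribute.numeric(float(observed))
    if isinstance(observed, int):
        return Attribute.recorded({observed})
    return Attribute.recorded(observed)


def differences_report(specimen: Mapping[int, Attribute], taxon: str,
                       dataset: Dataset) -> list[tuple[int, Attribute, Attribute]]:
    """Every character where specimen and taxon are both RECORDED and
    disjoint; an empty list means the specimen is consistent with the
    taxon."""
    record = dataset.taxon(taxon)
    out = []
    for c in sorted(specimen):
        if not dataset.has_character(c):
            continue
        s_attr = specimen[c]
        t_attr = record.attribute(c)
        if attributes_differ(s_attr, t_attr):
            out.append((c, s_attr, t_attr))
    return out
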