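"""Minimal diagnoses: smallest character sets separating one taxon from all
others at a given level.

A character set ``D`` is a valid level-``d`` diagnosis for taxon ``T`` when
every rival taxon differs from ``T`` (per the disjointness comparison) on at
least ``d`` characters of ``D``.  Exact mode finds a minimum-cardinality set
by branch and bound over the set-multicover formulation; greedy mode
iteratively adds the character that lifts the most below-level rivals.  Both
are deterministic.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

from .model import Dataset, attributes_differ

__all__ = [
    "DiagnosisMode", "TieBreak", "DiagnosisParams", "Diagnosis",
    "DiagnosisInfeasible", "InvalidDiagnosisError",
    "verify_diagnosis", "minimal_diagnosis", "diagnosis_feasibility",
]


class DiagnosisMode(str, enum.Enum):
    EXACT = "exact"
    GREEDY = "greedy"


class TieBreak(str, enum.Enum):
    LOWEST_NUMBER = "lowest-character-number"
    RELIABILITY = "highest-reliability-then-number"


@dataclass(frozen=True)
class DiagnosisParams:
    level: int = 1
    mode: DiagnosisMode = DiagnosisMode.EXACT
    tie_break: TieBreak = TieBreak.LOWEST_NUMBER

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("DiagLevel must be >= 1")


@dataclass
class Diagnosis:
    taxon: str
    level: int
    characters: list[int]
    attributes: dict[int, object]
    rival_margins: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.characters)


class DiagnosisInfeasible(RuntimeError):
    def __init__(self, taxon: str, level: int, blocking: dict[str, int]):
        self.taxon = taxon
        self.level = level
        self.blocking = blocking
        rivals = ", ".join(f"{r} ({c})" for r, c in sorted(blocking.items()))
        super().__init__(
            f"no level-{level} diagnosis exists for {taxon!r}; rivals with too "
            f"few distinguishing characters: {rivals}")


class InvalidDiagnosisError(ValueError):
    pass


def _difference_sets(dataset: Dataset, taxon: str,
                     characters: list[int] | None = None) -> dict[str, set[int]]:
    """rival -> set of characters (within ``characters``) where it provably
    differs from ``taxon``."""
    focal = dataset.taxon(taxon)
    pool = characters if characters is not None else dataset.character_numbers
    out: dict[str, set[int]] = {}
    for rival in dataset.taxa:
        if rival.name == taxon:
            continue
        out[rival.name] = {
            c for c in pool
            if attributes_differ(focal.attribute(c), rival.attribute(c))
        }
    return out


def verify_diagnosis(dataset: Dataset, taxon: str, characters: list[int],
                     level: int) -> tuple[bool, dict[str, int]]:
    """Check a candidate diagnosis; returns (valid, per-rival margins)."""
    focal = dataset.taxon(taxon)
    for c in characters:
        dataset.character(c)
        if not focal.attribute(c).is_recorded:
            raise InvalidDiagnosisError(
                f"character {c} is not RECORDED for {taxon!r}")
    diffs = _difference_sets(dataset, taxon, list(characters))
    margins = {r: len(s) for r, s in diffs.items()}
    return all(m >= level for m in margins.values()), margins


def diagnosis_feasibility(dataset: Dataset, taxon: str,
                          level: int) -> tuple[bool, dict[str, int]]:
    """Feasible iff every rival differs on >= level characters overall.
    Returns (feasible, blocking rivals with their totals)."""
    diffs = _difference_sets(dataset, taxon)
    blocking = {r: len(s) for r, s in diffs.items() if len(s) < level}
    return not blocking, blocking


def minimal_diagnosis(dataset: Dataset, taxon: str,
                      params: DiagnosisParams | None = None) -> Diagnosis:
    params = params or DiagnosisParams()
    feasible, blocking = diagnosis_feasibility(dataset, taxon, params.level)
    if not feasible:
        raise DiagnosisInfeasible(taxon, params.level, blocking)

    diffs = _difference_sets(dataset, taxon)
    # only characters that separate at least one rival can ever help
    useful = sorted({c for s in diffs.values() for c in s})
    useful = _order_candidates(dataset, useful, params.tie_break)

    if params.mode is DiagnosisMode.GREEDY:
        chosen = _greedy(diffs, useful, params.level)
    else:
        chosen = _branch_and_bound(diffs, useful, params.level)
        if chosen is None:  # pragma: no cover - b&b is complete; safety net
            chosen = _brute_force(diffs, useful, params.level)
    chosen = sorted(chosen)
    ok, margins = verify_diagnosis(dataset, taxon, chosen, params.level)
    assert ok, "internal error: constructed diagnosis failed verification"
    focal = dataset.taxon(taxon)
    return Diagnosis(
        taxon=taxon, level=params.level, characters=chosen,
        attributes={c: focal.attribute(c) for c in chosen},
        rival_margins=margins)


def _order_candidates(dataset: Dataset, chars: list[int],
                      tie_break: TieBreak) -> list[int]:
    if tie_break is TieBreak.RELIABILITY:
        return sorted(chars, key=lambda c: (-dataset.character(c).reliability, c))
    return sorted(chars)


def _greedy(diffs: dict[str, set[int]], candidates: list[int],
            level: int) -> list[int]:
    chosen: list[int] = []
    counts = {r: 0 for r in diffs}
    below = set(diffs)
    while below:
        best = None
        for c in candidates:
            if c in chosen:
                continue
            gain = sum(1 for r in below if c in diffs[r])
            if gain and (best is None or gain > best[0]):
                best = (gain, c)
        assert best is not None, "feasibility pre-checked"
        chosen.append(best[1])
        for r in list(below):
            if best[1] in diffs[r]:
                counts[r] += 1
                if counts[r] >= level:
                    below.discard(r)
    return chosen


def _branch_and_bound(diffs: dict[str, set[int]], candidates: list[int],
                      level: int) -> list[int] | None:
    """Minimum multicover: every rival covered >= level times."""
    rivals = sorted(diffs, key=lambda r: len(diffs[r]))
    greedy = _greedy(diffs, candidates, level)
    best: list[int] | None = list(greedy)

    counts0 = {r: 0 for r in rivals}

    def lower_bound(counts: dict[str, int]) -> int:
        deficit = max((level - counts[r] for r in rivals), default=0)
        return deficit  # need at least the worst single deficit many more

    def search(idx: int, chosen: list[int], counts: dict[str, int]) -> None:
        nonlocal best
        if all(counts[r] >= level for r in rivals):
            if best is None or len(chosen) < len(best):
                best = list(chosen)
            return
        if best is not None and len(chosen) + lower_bound(counts) >= len(best):
            return
        if idx >= len(candidates):
            return
        # feasibility of the remainder: every under-covered rival must still
        # have enough remaining candidate characters
        remaining = candidates[idx:]
        for r in rivals:
            if counts[r] < level:
                avail = sum(1 for c in remaining if c in diffs[r])
                if counts[r] + avail < level:
                    return
        c = candidates[idx]
        # branch: take c
        new_counts = dict(counts)
        useful = False
        for r in rivals:
            if c in diffs[r]:
                new_counts[r] += 1
                if counts[r] < level:
                    useful = True
        if useful:
            chosen.append(c)
            search(idx + 1, chosen, new_counts)
            chosen.pop()
        # branch: skip c
        search(idx + 1, chosen, counts)

    search(0, [], counts0)
    return best


def _brute_force(diffs: dict[str, set[int]], candidates: list[int],
                 level: int) -> list[int]:
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            if all(sum(1 for c in combo if c in diffs[r]) >= level
                   for r in diffs):
                return list(combo)
    raise AssertionError("feasibility pre-checked")
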