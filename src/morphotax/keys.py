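"""Dichotomous/polytomous identification keys: generation, routing,
rendering, and consistency checking.

Key generation recursively partitions the taxon set, at each node choosing
the usable character with the best score

    score(c) = E(c) * varywt**v * rbase**(r_c - 5) / reuse**u

where ``E`` is the Shannon entropy (normalized to [0, 1]) of the node taxa
across the character's realized states (polymorphic and unknown taxa are
multi-counted), ``v`` counts node taxa that would follow more than one lead,
``r_c`` is the character reliability, and ``u`` is the number of prior uses
of the character on the path.  ``abase`` is accepted for compatibility but
is a no-op hook (abundance weighting is not implemented).  The default
parameter values are RBASE=2.00, ABASE=1.00, REUSE=1.01, VARYWT=0.80 with
two confirmatory characters.

Routing follows every compatible lead (specimen-unknown is compatible with
everything); confirmatory statements are advisory and never block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import (
    Attribute, AttributeStatus, CharacterKind, Dataset,
)

__all__ = [
    "KeyGenParams", "Statement", "Lead", "Couplet", "Key",
    "KeyStructureError", "score_character", "build_key", "route_specimen",
    "RoutingResult", "check_key_consistency", "render_key",
]


class KeyStructureError(ValueError):
    pass


@dataclass(frozen=True)
class KeyGenParams:
    rbase: float = 2.00
    abase: float = 1.00
    reuse: float = 1.01
    varywt: float = 0.80
    n_confirmatory: int = 2
    max_depth: int = 64

    def __post_init__(self) -> None:
        if self.rbase <= 1.0:
            raise ValueError("rbase must be > 1")
        if self.reuse < 1.0:
            raise ValueError("reuse must be >= 1")
        if not 0.0 < self.varywt <= 1.0:
            raise ValueError("varywt must lie in (0, 1]")
        if self.n_confirmatory < 0:
            raise ValueError("n_confirmatory must be >= 0")


@dataclass(frozen=True)
class Statement:
    """One lead statement; ``character`` is None for text-only statements
    preserved verbatim from an encoded printed key."""
    character: int | None
    states: frozenset[int] = frozenset()
    text: str = ""

    def to_json(self) -> dict:
        obj: dict = {}
        if self.character is not None:
            obj["character"] = self.character
            obj["states"] = sorted(self.states)
        if self.text:
            obj["text"] = self.text
        return obj

    @classmethod
    def from_json(cls, obj: Mapping) -> "Statement":
        return cls(
            character=obj.get("character"),
            states=frozenset(obj.get("states", ())),
            text=obj.get("text", ""),
        )


@dataclass(frozen=True)
class Destination:
    couplet: int | None = None
    taxon: str | None = None
    authority: str = ""
    raw: str = ""

    @property
    def is_terminal(self) -> bool:
        return self.taxon is not None

    def to_json(self) -> dict:
        if self.couplet is not None:
            return {"couplet": self.couplet}
        if self.taxon is not None:
            obj: dict = {"taxon": self.taxon}
            if self.authority:
                obj["authority"] = self.authority
            return obj
        return {"raw": self.raw}

    @classmethod
    def from_json(cls, obj: Mapping) -> "Destination":
        if "couplet" in obj:
            return cls(couplet=int(obj["couplet"]))
        if "taxon" in obj:
            return cls(taxon=obj["taxon"], authority=obj.get("authority", ""))
        return cls(raw=obj.get("raw", ""))


@dataclass
class Lead:
    statements: list[Statement]
    destination: Destination
    text: str = ""

    @property
    def primary(self) -> Statement:
        return self.statements[0]

    def to_json(self) -> dict:
        obj: dict = {
            "statements": [s.to_json() for s in self.statements],
            "destination": self.destination.to_json(),
        }
        if self.text:
            obj["text"] = self.text
        return obj

    @classmethod
    def from_json(cls, obj: Mapping) -> "Lead":
        return cls(
            statements=[Statement.from_json(s) for s in obj["statements"]],
            destination=Destination.from_json(obj["destination"]),
            text=obj.get("text", ""),
        )


@dataclass
class Couplet:
    number: int
    parent: int
    leads: list[Lead]

    def to_json(self) -> dict:
        return {"number": self.number, "parent": self.parent,
                "leads": [l.to_json() for l in self.leads]}

    @classmethod
    def from_json(cls, obj: Mapping) -> "Couplet":
        return cls(number=int(obj["number"]), parent=int(obj.get("parent", 0)),
                   leads=[Lead.from_json(l) for l in obj["leads"]])


@dataclass
class Key:
    couplets: dict[int, Couplet]
    title: str = ""
    inseparable: list[list[str]] = field(default_factory=list)
    anomalies: list[str] = field(default_factory=list)

    @property
    def root(self) -> int:
        return min(self.couplets)

    def terminals(self) -> list[Destination]:
        return [l.destination for c in self.couplets.values() for l in c.leads
                if l.destination.is_terminal]

    def terminal_taxa(self) -> set[str]:
        return {d.taxon for d in self.terminals()}  # type: ignore[misc]

    def to_json(self) -> dict:
        return {
            "format": "morphotax-key",
            "version": "1",
            "title": self.title,
            "couplets": [self.couplets[n].to_json() for n in sorted(self.couplets)],
            "inseparable": self.inseparable,
            "anomalies": self.anomalies,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "Key":
        couplets = {}
        for c in obj["couplets"]:
            cp = Couplet.from_json(c)
            couplets[cp.number] = cp
        return cls(
            couplets=couplets,
            title=obj.get("title", ""),
            inseparable=[list(g) for g in obj.get("inseparable", ())],
            anomalies=list(obj.get("anomalies", ())),
        )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _realized_states(dataset: Dataset, taxa: Iterable[str], c: int) -> set[int]:
    out: set[int] = set()
    for t in taxa:
        a = dataset.attribute(t, c)
        if a.is_recorded and a.states:
            out |= a.states
    return out


def score_character(node_taxa: Iterable[str], c: int, usage: Mapping[int, int],
                    dataset: Dataset, params: KeyGenParams) -> float:
    """Score ``c`` at a node; raises ValueError if the character is unusable
    (numeric, or no node taxon records it)."""
    char = dataset.character(c)
    if char.kind is not CharacterKind.MULTISTATE:
        raise ValueError(f"character {c} is numeric, not usable in a key")
    taxa = sorted(node_taxa)
    realized = sorted(_realized_states(dataset, taxa, c))
    if not realized:
        raise ValueError(f"character {c} is unknown for every node taxon")

    counts = {s: 0 for s in realized}
    n_vary = 0
    for t in taxa:
        a = dataset.attribute(t, c)
        if a.is_recorded and a.states:
            follows = sorted(a.states & set(realized))
        else:
            follows = realized  # unknown/inapplicable follow every lead
        if len(follows) > 1:
            n_vary += 1
        for s in follows:
            counts[s] += 1

    total = sum(counts.values())
    entropy = 0.0
    for s in realized:
        if counts[s]:
            p = counts[s] / total
            entropy -= p * math.log(p)
    max_entropy = math.log(len(realized)) if len(realized) > 1 else 1.0
    e_norm = entropy / max_entropy if len(realized) > 1 else 0.0

    r_c = char.reliability
    u = usage.get(c, 0)
    return (e_norm * (params.varywt ** n_vary)
            * (params.rbase ** (r_c - 5.0)) / (params.reuse ** u))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def build_key(dataset: Dataset, params: KeyGenParams | None = None,
              title: str = "") -> Key:
    params = params or KeyGenParams()
    if len(dataset.taxa) < 2:
        raise ValueError("need at least two taxa to build a key")

    couplets: dict[int, Couplet] = {}
    inseparable: list[list[str]] = []
    counter = {"next": 1}
    authority = {t.name: t.authority for t in dataset.taxa}

    def split(taxa: list[str], c: int) -> dict[int, list[str]]:
        realized = sorted(_realized_states(dataset, taxa, c))
        leads: dict[int, list[str]] = {s: [] for s in realized}
        for t in taxa:
            a = dataset.attribute(t, c)
            if a.is_recorded and a.states:
                follows = sorted(a.states & set(realized))
            else:
                follows = realized
            for s in follows:
                leads[s].append(t)
        return leads

    def candidates(taxa: list[str], usage: dict[int, int]) -> list[tuple[float, int]]:
        out = []
        for char in dataset.multistate_characters():
            c = char.number
            try:
                s = score_character(taxa, c, usage, dataset, params)
            except ValueError:
                continue
            if s <= 0.0:
                continue
            leads = split(taxa, c)
            if len(leads) < 2:
                continue
            if any(len(v) == len(taxa) for v in leads.values()):
                continue  # no progress on some lead: would not terminate
            out.append((s, c))
        # highest score wins; ties break to the lowest character number
        out.sort(key=lambda sc: (-sc[0], sc[1]))
        return out

    def confirmatory_for(taxa: list[str], p: int,
                         leads: dict[int, list[str]]) -> dict[int, list[Statement]]:
        """Per-lead confirmatory statements (up to n_confirmatory chars)."""
        extra: dict[int, list[Statement]] = {s: [] for s in leads}
        if params.n_confirmatory == 0:
            return extra
        n_found = 0
        for char in dataset.multistate_characters():
            c = char.number
            if c == p:
                continue
            mapping: dict[int, int] = {}
            seen_c: dict[int, int] = {}
            ok = True
            n_mono = 0
            for s, members in leads.items():
                for t in members:
                    ap = dataset.attribute(t, p)
                    ac = dataset.attribute(t, c)
                    if not (ap.is_recorded and len(ap.states) == 1
                            and ac.is_recorded and len(ac.states) == 1):
                        continue
                    if next(iter(ap.states)) != s:
                        continue
                    n_mono += 1
                    cs = next(iter(ac.states))
                    if s in mapping and mapping[s] != cs:
                        ok = False
                        break
                    if cs in seen_c and seen_c[cs] != s:
                        ok = False  # not injective: same grouping required
                        break
                    mapping[s] = cs
                    seen_c[cs] = s
                if not ok:
                    break
            if not ok or len(mapping) < 2 or n_mono < 2:
                continue
            for s in leads:
                if s in mapping:
                    extra[s].append(Statement(character=c,
                                              states=frozenset({mapping[s]})))
            n_found += 1
            if n_found >= params.n_confirmatory:
                break
        return extra

    def recurse(taxa: list[str], usage: dict[int, int], depth: int,
                parent: int) -> Destination:
        taxa = sorted(set(taxa))
        if len(taxa) == 1:
            return Destination(taxon=taxa[0], authority=authority[taxa[0]])
        cands = candidates(taxa, usage)
        if not cands or depth >= params.max_depth:
            inseparable.append(list(taxa))
            return Destination(raw="inseparable: " + ", ".join(taxa))
        _, c = cands[0]
        number = counter["next"]
        counter["next"] += 1
        couplet = Couplet(number=number, parent=parent, leads=[])
        couplets[number] = couplet
        leads = split(taxa, c)
        confirm = confirmatory_for(taxa, c, leads)
        new_usage = dict(usage)
        new_usage[c] = new_usage.get(c, 0) + 1
        for s in sorted(leads):
            dest = recurse(leads[s], new_usage, depth + 1, number)
            stmts = [Statement(character=c, states=frozenset({s}))]
            stmts.extend(confirm[s])
            couplet.leads.append(Lead(statements=stmts, destination=dest))
        return Destination(couplet=number)

    root_dest = recurse(dataset.taxon_names, {}, 0, 0)
    if root_dest.couplet is None:
        # the whole dataset is inseparable; represent as a single flagged
        # couplet so the key object is still well-formed
        raise KeyStructureError("no character separates any taxa")
    return Key(couplets=couplets, title=title or f"Key to {dataset.title}",
               inseparable=inseparable)


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

@dataclass
class RoutingResult:
    terminals: list[tuple[Destination, list[tuple[int, int]]]]
    confirmatory_disagreements: list[tuple[int, int, Statement]]
    flagged: list[str] = field(default_factory=list)

    def taxa(self) -> set[str]:
        return {d.taxon for d, _ in self.terminals if d.taxon is not None}


def _compatible(statement: Statement, attributes: Mapping[int, Attribute]) -> bool:
    if statement.character is None:
        return True  # text-only statements cannot block
    a = attributes.get(statement.character)
    if a is None or not a.is_recorded or not a.states:
        return True  # unknown specimen data is compatible with everything
    return bool(a.states & statement.states)


def route_specimen(key: Key, attributes: Mapping[int, Attribute]) -> RoutingResult:
    terminals: list[tuple[Destination, list[tuple[int, int]]]] = []
    disagreements: list[tuple[int, int, Statement]] = []
    flagged: list[str] = []

    stack: list[tuple[int, list[tuple[int, int]]]] = [(key.root, [])]
    while stack:
        number, path = stack.pop()
        if number not in key.couplets:
            raise KeyStructureError(f"dangling destination: couplet {number}")
        if any(n == number for n, _ in path):
            flagged.append(f"cycle at couplet {number}; branch abandoned")
            continue
        couplet = key.couplets[number]
        for li, lead in enumerate(couplet.leads):
            if not _compatible(lead.primary, attributes):
                continue
            for conf in lead.statements[1:]:
                if not _compatible(conf, attributes):
                    disagreements.append((number, li, conf))
            dest = lead.destination
            new_path = path + [(number, li)]
            if dest.couplet is not None:
                stack.append((dest.couplet, new_path))
            elif dest.is_terminal:
                terminals.append((dest, new_path))
            else:
                flagged.append(
                    f"couplet {number} lead {li}: unresolved destination "
                    f"{dest.raw!r}")
    terminals.sort(key=lambda tp: (tp[0].taxon or "", tp[1]))
    return RoutingResult(terminals=terminals,
                         confirmatory_disagreements=disagreements,
                         flagged=flagged)


# ---------------------------------------------------------------------------
# Consistency checking and rendering
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    contradictions: list[tuple[str, int, Statement]]
    unreached: list[str]

    @property
    def ok(self) -> bool:
        return not self.contradictions and not self.unreached


def check_key_consistency(key: Key, dataset: Dataset) -> ConsistencyReport:
    """Route every taxon's own attributes; report statement contradictions on
    followed leads and taxa that never reach a terminal of their own name."""
    contradictions: list[tuple[str, int, Statement]] = []
    unreached: list[str] = []
    for t in dataset.taxa:
        result = route_specimen(key, t.attributes)
        if t.name not in result.taxa():
            unreached.append(t.name)
        for number, _li, stmt in result.confirmatory_disagreements:
            a = t.attributes.get(stmt.character)  # type: ignore[arg-type]
            if a is not None and a.is_recorded and a.states \
                    and not a.states & stmt.states:
                contradictions.append((t.name, number, stmt))
    return ConsistencyReport(contradictions=contradictions, unreached=unreached)


def _statement_text(statement: Statement, dataset: Dataset | None) -> str:
    if statement.text:
        return statement.text
    if statement.character is None:
        return "(unstated)"
    if dataset is None or not dataset.has_character(statement.character):
        states = "/".join(str(s) for s in sorted(statement.states))
        return f"character {statement.character} = {states}"
    char = dataset.character(statement.character)
    states = ", or ".join(char.state_label(s) for s in sorted(statement.states))
    return f"{char.label} {states}"


def render_key(key: Key, dataset: Dataset | None = None,
               markdown: bool = False) -> str:
    """Two-column "n(parent)" layout with en-dash alternate leads and bold
    terminal names."""
    lines: list[str] = []
    if key.title:
        lines.append(key.title)
        lines.append("")
    for number in sorted(key.couplets):
        couplet = key.couplets[number]
        for li, lead in enumerate(couplet.leads):
            head = f"{number}({couplet.parent})" if li == 0 else "–"
            body = "; ".join(_statement_text(s, dataset) for s in lead.statements)
            dest = lead.destination
            if dest.is_terminal:
                name = f"{dest.taxon} {dest.authority}".strip()
                target = f"***{dest.taxon}* {dest.authority}**".strip() \
                    if markdown else name
            elif dest.couplet is not None:
                target = f"**{dest.couplet}**" if markdown else str(dest.couplet)
            else:
                target = dest.raw
            lines.append(f"{head}\t{body}\t{target}")
    return "\n".join(lines) + "\n"
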