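"""A documented DELTA-dialect reader/writer.

Only a subset of the classic DELTA format is supported, chosen to make
write -> read lossless for any valid dataset:

Character list file::

    #<n>. <label>/
    <k>. <state label>/          (multistate only; k is the 1-based code)
    <unit: chaetiger>            (numeric only, optional)
    <reliability: 7>             (optional, default 5)
    <applicable when: 5,1/2>     (optional dependency, repeatable)
    <section: Chaetae>           (optional)

Items file::

    #<m>. <Taxon name> <<authority>>/
    1,2 4,1/2 105,2-4 7,U 6,- 3,1<comment text>
    <meta key: value>            (optional, repeatable)

Attribute tokens: ``c,s1/s2`` alternative states, ``c,lo-hi`` numeric range,
``c,U`` unknown, ``c,-`` inapplicable, and an optional trailing ``<...>``
comment.  Angle brackets inside labels, comments, or metadata are not
supported and are rejected at write time.  Unsupported classic-DELTA
directives encountered while reading are collected and reported, never
silently misread.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ..model import (
    Attribute, AttributeStatus, CharacterDefinition, CharacterKind, Dataset,
    Dependency, TaxonRecord,
)

__all__ = ["read_delta", "write_delta", "DeltaParseError"]


class DeltaParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


def _check_clean(text: str, what: str) -> str:
    if "<" in text or ">" in text:
        raise ValueError(f"{what} contains angle brackets, unsupported by the "
                         f"DELTA dialect: {text!r}")
    if "\n" in text or text.endswith("/"):
        raise ValueError(f"{what} cannot span lines or end with '/': {text!r}")
    return text


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

def write_delta(dataset: Dataset) -> tuple[str, str]:
    """Return ``(character list text, items text)``."""
    chars_lines: list[str] = [f"*TITLE {_check_clean(dataset.title, 'title')}/"]
    for c in dataset.characters:
        chars_lines.append(f"#{c.number}. {_check_clean(c.label, 'label')}/")
        for k, s in enumerate(c.states, start=1):
            chars_lines.append(f"{k}. {_check_clean(s, 'state label')}/")
        if c.kind is CharacterKind.NUMERIC and c.unit:
            chars_lines.append(f"<unit: {_check_clean(c.unit, 'unit')}>")
        if c.reliability != 5.0:
            chars_lines.append(f"<reliability: {_fmt_num(c.reliability)}>")
        for dep in c.dependencies:
            states = "/".join(str(s) for s in sorted(dep.states))
            chars_lines.append(f"<applicable when: {dep.controller},{states}>")
        if c.section:
            chars_lines.append(f"<section: {_check_clean(c.section, 'section')}>")
        chars_lines.append("")

    item_lines: list[str] = []
    for m, t in enumerate(dataset.taxa, start=1):
        name = _check_clean(t.name, "taxon name")
        auth = f" <<{_check_clean(t.authority, 'authority')}>>" if t.authority else ""
        item_lines.append(f"#{m}. {name}{auth}/")
        tokens = []
        for n in sorted(t.attributes):
            a = t.attributes[n]
            if a.status is AttributeStatus.UNKNOWN:
                spec = "U"
            elif a.status is AttributeStatus.INAPPLICABLE:
                spec = "-"
            elif a.states:
                spec = "/".join(str(s) for s in sorted(a.states))
            else:
                lo, hi = a.range  # type: ignore[misc]
                spec = _fmt_num(lo) if lo == hi else f"{_fmt_num(lo)}-{_fmt_num(hi)}"
            tok = f"{n},{spec}"
            if a.comment:
                tok += f"<{_check_clean(a.comment, 'comment')}>"
            tokens.append(tok)
        item_lines.append(" ".join(tokens))
        for k in sorted(t.metadata):
            item_lines.append(
                f"<meta {_check_clean(k, 'metadata key')}: "
                f"{_check_clean(t.metadata[k], 'metadata value')}>")
        item_lines.append("")
    return "\n".join(chars_lines) + "\n", "\n".join(item_lines) + "\n"


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------

_HEAD = re.compile(r"^#(\d+)\.\s+(.*)/\s*$")
_STATE = re.compile(r"^(\d+)\.\s+(.*)/\s*$")
_ANNOT = re.compile(r"^<(\w[\w ]*?):\s*(.*)>\s*$")
_TOKEN = re.compile(r"(\d+),([^<\s]+)(?:<([^>]*)>)?")


def read_delta(chars_text: str, items_text: str) -> Dataset:
    characters, title, skipped = _read_characters(chars_text)
    char_by_num = {c.number: c for c in characters}
    taxa = _read_items(items_text, char_by_num)
    ds = Dataset(characters=characters, taxa=taxa, title=title)
    ds.skipped_directives = skipped  # type: ignore[attr-defined]
    return ds


def _read_characters(text: str):
    characters: list[CharacterDefinition] = []
    title = ""
    skipped: list[str] = []
    cur: dict | None = None

    def flush() -> None:
        if cur is None:
            return
        kind = CharacterKind.MULTISTATE if cur["states"] else CharacterKind.NUMERIC
        characters.append(CharacterDefinition(
            number=cur["number"], label=cur["label"], kind=kind,
            states=tuple(cur["states"]), unit=cur["unit"],
            reliability=cur["reliability"], dependencies=tuple(cur["deps"]),
            section=cur["section"]))

    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("*TITLE "):
            title = line[len("*TITLE "):].rstrip("/").rstrip()
            continue
        if line.startswith("*"):
            skipped.append(line)
            continue
        m = _HEAD.match(line)
        if m:
            flush()
            cur = {"number": int(m.group(1)), "label": m.group(2).strip(),
                   "states": [], "unit": "", "reliability": 5.0,
                   "deps": [], "section": ""}
            continue
        if cur is None:
            raise DeltaParseError(f"unexpected content {line!r}", lineno)
        a = _ANNOT.match(line)
        if a:
            key, value = a.group(1), a.group(2).strip()
            if key == "unit":
                cur["unit"] = value
            elif key == "reliability":
                cur["reliability"] = float(value)
            elif key == "applicable when":
                ctrl_s, states_s = value.split(",", 1)
                cur["deps"].append(Dependency(
                    int(ctrl_s), frozenset(int(x) for x in states_s.split("/"))))
            elif key == "section":
                cur["section"] = value
            else:
                skipped.append(line)
            continue
        s = _STATE.match(line)
        if s:
            code = int(s.group(1))
            if code != len(cur["states"]) + 1:
                raise DeltaParseError(
                    f"state {code} out of order for character {cur['number']}",
                    lineno)
            cur["states"].append(s.group(2).strip())
            continue
        raise DeltaParseError(f"cannot parse {line!r}", lineno)
    flush()
    return characters, title, skipped


_ITEM_HEAD = re.compile(r"^#(\d+)\.\s+(.*)/\s*$")


def _read_items(text: str, char_by_num: dict[int, CharacterDefinition]):
    taxa: list[TaxonRecord] = []
    cur: TaxonRecord | None = None
    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _ITEM_HEAD.match(line)
        if m:
            body = m.group(2).strip()
            authority = ""
            am = re.search(r"<<(.*)>>\s*$", body)
            if am:
                authority = am.group(1)
                body = body[: am.start()].strip()
            cur = TaxonRecord(name=body, authority=authority)
            taxa.append(cur)
            continue
        if cur is None:
            raise DeltaParseError(f"attribute data before any item: {line!r}",
                                  lineno)
        meta = re.match(r"^<meta ([^:>]+):\s*(.*)>\s*$", line)
        if meta:
            cur.metadata[meta.group(1).strip()] = meta.group(2).strip()
            continue
        pos = 0
        for tok in _TOKEN.finditer(line):
            if line[pos:tok.start()].strip():
                raise DeltaParseError(
                    f"cannot parse {line[pos:tok.start()]!r}", lineno)
            pos = tok.end()
            n = int(tok.group(1))
            spec = tok.group(2)
            comment = tok.group(3) or ""
            char = char_by_num.get(n)
            if char is None:
                raise DeltaParseError(
                    f"item {cur.name!r} references undeclared character {n}",
                    lineno)
            cur.attributes[n] = _parse_spec(spec, comment, char, cur.name, lineno)
        if line[pos:].strip():
            raise DeltaParseError(f"cannot parse {line[pos:]!r}", lineno)
    return taxa


def _parse_spec(spec: str, comment: str, char: CharacterDefinition,
                taxon: str, lineno: int) -> Attribute:
    if spec == "U":
        return Attribute.unknown(comment)
    if spec == "-":
        return Attribute.inapplicable(comment)
    if char.kind is CharacterKind.MULTISTATE:
        try:
            states = [int(x) for x in spec.split("/")]
        except ValueError:
            raise DeltaParseError(
                f"item {taxon!r}: bad state spec {spec!r} for character "
                f"{char.number}", lineno) from None
        bad = [s for s in states if not 1 <= s <= char.n_states]
        if bad:
            raise DeltaParseError(
                f"item {taxon!r}: state(s) {bad} undeclared for character "
                f"{char.number}", lineno)
        return Attribute.recorded(states, comment)
    m = re.match(r"^(-?\d+(?:\.\d+)?)(?:-(-?\d+(?:\.\d+)?))?$", spec)
    if not m:
        raise DeltaParseError(
            f"item {taxon!r}: bad numeric spec {spec!r} for character "
            f"{char.number}", lineno)
    lo = float(m.group(1))
    hi = float(m.group(2)) if m.group(2) else lo
    return Attribute.numeric(lo, hi, comment)
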