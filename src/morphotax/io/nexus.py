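"""NEXUS export/import for morphological matrices.

The writer emits ``TAXA`` and ``CHARACTERS`` blocks with ``CHARSTATELABELS``;
numeric (meristic) characters are excluded by default.  Polymorphic cells
are rendered as brace-enclosed multi-symbol groups, UNKNOWN as the missing
symbol (default ``?``) and INAPPLICABLE as the gap symbol (default ``-``),
the common morphological-matrix convention.  Labels are emitted in full by
default; ``full_labels=False`` reproduces the legacy 30-character
truncation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ..model import (
    Attribute, AttributeStatus, CharacterDefinition, CharacterKind, Dataset,
    TaxonRecord,
)

__all__ = ["NexusExportOptions", "NexusExportError", "NexusParseError",
           "write_nexus", "read_nexus"]


class NexusExportError(ValueError):
    pass


class NexusParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class NexusExportOptions:
    exclude_numeric: bool = True
    full_labels: bool = True
    symbols: str = "123456789"
    missing: str = "?"
    gap: str = "-"
    interleave: bool = False


def _quote(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _trunc(label: str, full: bool) -> str:
    return label if full else label[:30]


def write_nexus(dataset: Dataset, options: NexusExportOptions | None = None) -> str:
    options = options or NexusExportOptions()
    if not dataset.taxa:
        raise NexusExportError("dataset has no taxa")
    chars = [c for c in dataset.characters
             if not (options.exclude_numeric and c.kind is CharacterKind.NUMERIC)]
    if any(c.kind is CharacterKind.NUMERIC for c in chars):
        raise NexusExportError(
            "NEXUS standard matrices cannot carry numeric characters; "
            "use exclude_numeric=True")
    if not chars:
        raise NexusExportError("no exportable characters")
    max_states = max(c.n_states for c in chars)
    if max_states > len(options.symbols):
        raise NexusExportError(
            f"{max_states} states exceed the {len(options.symbols)} configured "
            f"symbols")

    out: list[str] = ["#NEXUS", ""]
    out.append("BEGIN TAXA;")
    out.append(f"    DIMENSIONS NTAX={len(dataset.taxa)};")
    out.append("    TAXLABELS")
    for t in dataset.taxa:
        out.append(f"        {_quote(t.name)}")
    out.append("    ;")
    out.append("END;")
    out.append("")
    out.append("BEGIN CHARACTERS;")
    out.append(f"    DIMENSIONS NCHAR={len(chars)};")
    fmt = (f'    FORMAT DATATYPE=STANDARD SYMBOLS="{options.symbols}" '
           f'MISSING={options.missing} GAP={options.gap}')
    if options.interleave:
        fmt += " INTERLEAVE"
    out.append(fmt + ";")
    out.append("    CHARSTATELABELS")
    label_lines = []
    for i, c in enumerate(chars, start=1):
        states = " ".join(_quote(_trunc(s, options.full_labels)) for s in c.states)
        label_lines.append(
            f"        {i} {_quote(_trunc(c.label, options.full_labels))} / {states}")
    out.append(",\n".join(label_lines))
    out.append("    ;")
    out.append("    MATRIX")

    name_w = max(len(_quote(t.name)) for t in dataset.taxa) + 2
    rows = {t.name: _row_symbols(t, chars, options) for t in dataset.taxa}
    if options.interleave:
        block = 60
        for start in range(0, len(chars), block):
            for t in dataset.taxa:
                chunk = "".join(rows[t.name][start:start + block])
                out.append(f"        {_quote(t.name):<{name_w}}{chunk}")
            out.append("")
        if out[-1] == "":
            out.pop()
    else:
        for t in dataset.taxa:
            out.append(f"        {_quote(t.name):<{name_w}}{''.join(rows[t.name])}")
    out.append("    ;")
    out.append("END;")
    out.append("")
    return "\n".join(out)


def _row_symbols(taxon: TaxonRecord, chars: list[CharacterDefinition],
                 options: NexusExportOptions) -> list[str]:
    syms: list[str] = []
    for c in chars:
        a = taxon.attribute(c.number)
        if a.status is AttributeStatus.UNKNOWN:
            syms.append(options.missing)
        elif a.status is AttributeStatus.INAPPLICABLE:
            syms.append(options.gap)
        elif len(a.states) == 1:
            syms.append(options.symbols[next(iter(a.states)) - 1])
        else:
            group = "".join(options.symbols[s - 1] for s in sorted(a.states))
            syms.append("{" + group + "}")
    return syms


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------

def read_nexus(text: str) -> Dataset:
    """Parse a NEXUS CHARACTERS (or DATA) block into a Dataset.

    Only standard-datatype matrices are supported; unknown/gap symbols map
    back to UNKNOWN/INAPPLICABLE.  Files without CHARSTATELABELS get
    auto-named characters (``char_n``) and states (``state_k``); the dataset
    then carries a ``read_warnings`` list noting the fallback.
    """
    toks = _tokenize(text)
    if not toks or toks[0][0].upper() != "#NEXUS":
        raise NexusParseError("missing #NEXUS header",
                              toks[0][1] if toks else 1)
    i = 1
    ntax = nchar = None
    taxlabels: list[str] = []
    charlabels: dict[int, tuple[str, list[str]]] = {}
    symbols = "0123456789"
    missing, gap = "?", "-"
    matrix_rows: dict[str, str] = {}
    row_order: list[str] = []
    warnings: list[str] = []

    def expect(value: str) -> None:
        nonlocal i
        if i >= len(toks) or toks[i][0].upper() != value:
            line = toks[i][1] if i < len(toks) else toks[-1][1]
            found = toks[i][0] if i < len(toks) else "<eof>"
            raise NexusParseError(f"expected {value!r}, found {found!r}", line)
        i += 1

    while i < len(toks):
        tok, line = toks[i]
        if tok.upper() != "BEGIN":
            i += 1
            continue
        block = toks[i + 1][0].upper()
        i += 2
        expect(";")
        if block not in ("TAXA", "CHARACTERS", "DATA"):
            while i < len(toks) and toks[i][0].upper() != "END":
                i += 1
            i += 1
            continue
        # inside a relevant block: consume command by command
        while i < len(toks):
            cmd, cmd_line = toks[i]
            cu = cmd.upper()
            if cu == "END" or cu == "ENDBLOCK":
                i += 1
                if i < len(toks) and toks[i][0] == ";":
                    i += 1
                break
            j = i + 1
            body = []
            while j < len(toks) and toks[j][0] != ";":
                body.append(toks[j])
                j += 1
            if j >= len(toks):
                raise NexusParseError(f"unterminated {cmd} command", cmd_line)
            if cu == "DIMENSIONS":
                for b, _ in body:
                    m = re.fullmatch(r"(?i)NTAX=(\d+)", b)
                    if m:
                        ntax = int(m.group(1))
                    m = re.fullmatch(r"(?i)NCHAR=(\d+)", b)
                    if m:
                        nchar = int(m.group(1))
            elif cu == "TAXLABELS":
                taxlabels = [b for b, _ in body]
            elif cu == "FORMAT":
                for b, bl in body:
                    m = re.fullmatch(r"(?i)SYMBOLS=(.+)", b)
                    if m:
                        symbols = m.group(1).strip('"')
                    m = re.fullmatch(r"(?i)MISSING=(.)", b)
                    if m:
                        missing = m.group(1)
                    m = re.fullmatch(r"(?i)GAP=(.)", b)
                    if m:
                        gap = m.group(1)
                    m = re.fullmatch(r"(?i)DATATYPE=(\w+)", b)
                    if m and m.group(1).upper() != "STANDARD":
                        raise NexusParseError(
                            f"unsupported datatype {m.group(1)}", bl)
            elif cu == "CHARSTATELABELS":
                charlabels = _parse_charstatelabels(body)
            elif cu == "MATRIX":
                k = 0
                while k < len(body):
                    name = body[k][0]
                    k += 1
                    cells: list[str] = []
                    while k < len(body) and not _is_name_token(body[k][0], symbols, missing, gap):
                        cells.append(body[k][0])
                        k += 1
                    if name not in matrix_rows:
                        matrix_rows[name] = ""
                        row_order.append(name)
                    matrix_rows[name] += "".join(cells)
            i = j + 1

    if nchar is None:
        raise NexusParseError("no DIMENSIONS NCHAR found")
    if not row_order:
        raise NexusParseError("no MATRIX rows found")
    if ntax is not None and len(row_order) != ntax:
        raise NexusParseError(
            f"matrix has {len(row_order)} taxa but DIMENSIONS declares {ntax}")

    if not charlabels:
        warnings.append("no CHARSTATELABELS: characters auto-named char_n")

    characters = []
    for n in range(1, nchar + 1):
        label, states = charlabels.get(n, (f"char_{n}", []))
        n_states = max(len(states), 2)
        # ensure enough states to cover symbols actually used later; grow lazily
        characters.append({"label": label, "states": list(states),
                           "n_states": n_states})

    taxa: list[TaxonRecord] = []
    sym_index = {s: k + 1 for k, s in enumerate(symbols)}
    parsed_rows: dict[str, list[Attribute | None]] = {}
    for name in row_order:
        cells = _split_cells(matrix_rows[name], missing, gap)
        if len(cells) != nchar:
            raise NexusParseError(
                f"taxon {name!r}: {len(cells)} cells, expected {nchar}")
        attrs: list[Attribute | None] = []
        for n, cell in enumerate(cells, start=1):
            if cell == missing:
                attrs.append(Attribute.unknown())
            elif cell == gap:
                attrs.append(Attribute.inapplicable())
            else:
                try:
                    states = {sym_index[s] for s in cell}
                except KeyError as exc:
                    raise NexusParseError(
                        f"taxon {name!r}, character {n}: unknown symbol "
                        f"{exc.args[0]!r}") from None
                characters[n - 1]["n_states"] = max(
                    characters[n - 1]["n_states"], max(states))
                attrs.append(Attribute.recorded(states))
        parsed_rows[name] = attrs

    char_defs = []
    for n, c in enumerate(characters, start=1):
        states = list(c["states"])
        while len(states) < c["n_states"]:
            states.append(f"state_{len(states) + 1}")
        char_defs.append(CharacterDefinition(
            number=n, label=c["label"], states=tuple(states)))

    for name in row_order:
        taxa.append(TaxonRecord(
            name=_unquote(name),
            attributes={n: a for n, a in enumerate(parsed_rows[name], start=1)
                        if a is not None}))

    ds = Dataset(characters=char_defs, taxa=taxa, title="")
    ds.read_warnings = warnings  # type: ignore[attr-defined]
    return ds


def _is_name_token(tok: str, symbols: str, missing: str, gap: str) -> bool:
    allowed = set(symbols) | {missing, gap, "{", "}", "(", ")"}
    return any(ch not in allowed for ch in tok)


def _split_cells(row: str, missing: str, gap: str) -> list[str]:
    cells: list[str] = []
    k = 0
    while k < len(row):
        ch = row[k]
        if ch in "{(":
            close = "}" if ch == "{" else ")"
            end = row.find(close, k)
            if end < 0:
                raise NexusParseError(f"unterminated state group in {row!r}")
            cells.append(row[k + 1:end])
            k = end + 1
        else:
            cells.append(ch)
            k += 1
    return cells


def _parse_charstatelabels(body):
    # body: tokens "1 label / s1 s2 , 2 label / s1 s2 ..."
    out: dict[int, tuple[str, list[str]]] = {}
    groups: list[list[str]] = [[]]
    for tok, _ in body:
        if tok == ",":
            groups.append([])
        else:
            groups[-1].append(tok)
    for g in groups:
        if not g:
            continue
        num = int(g[0])
        if "/" in g:
            sep = g.index("/")
            label = " ".join(_unquote(x) for x in g[1:sep]) or f"char_{num}"
            states = [_unquote(x) for x in g[sep + 1:]]
        else:
            label = " ".join(_unquote(x) for x in g[1:]) or f"char_{num}"
            states = []
        out[num] = (label, states)
    return out


def _unquote(tok: str) -> str:
    if tok.startswith("'") and tok.endswith("'") and len(tok) >= 2:
        return tok[1:-1].replace("''", "'")
    return tok


def _tokenize(text: str) -> list[tuple[str, int]]:
    """NEXUS tokens with line numbers; comments [] removed, quotes kept."""
    toks: list[tuple[str, int]] = []
    line = 1
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            i += 1
        elif ch.isspace():
            i += 1
        elif ch == "[":
            depth = 1
            i += 1
            while i < n and depth:
                if text[i] == "[":
                    depth += 1
                elif text[i] == "]":
                    depth -= 1
                elif text[i] == "\n":
                    line += 1
                i += 1
        elif ch == "'":
            j = i + 1
            buf = ["'"]
            while j < n:
                if text[j] == "'" and j + 1 < n and text[j + 1] == "'":
                    buf.append("''")
                    j += 2
                elif text[j] == "'":
                    buf.append("'")
                    j += 1
                    break
                else:
                    if text[j] == "\n":
                        line += 1
                    buf.append(text[j])
                    j += 1
            else:
                raise NexusParseError("unterminated quoted token", line)
            toks.append(("".join(buf), line))
            i = j
        elif ch in ";,/":
            toks.append((ch, line))
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in ";,[/'":
                j += 1
            toks.append((text[i:j], line))
            i = j
    return toks
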