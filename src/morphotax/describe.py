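"""Natural-language taxon descriptions generated from the coded matrix.

A description is a concatenation of "<character label> <state label>"
sentences for every RECORDED attribute, traversed in ascending character
number within section order; UNKNOWN and INAPPLICABLE cells are omitted.
Output is deterministic: identical inputs yield byte-identical text.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Attribute, CharacterDefinition, CharacterKind, Dataset

__all__ = ["DescriptionStyle", "describe_taxon", "describe_dataset"]


@dataclass(frozen=True)
class DescriptionStyle:
    include_comments: bool = False
    section_headings: bool = False
    polymorphism_joiner: str = ", or "
    sentence_terminator: str = ". "
    markdown: bool = False

    def __post_init__(self) -> None:
        if not self.polymorphism_joiner:
            raise ValueError("polymorphism joiner must be non-empty")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def _sentence(char: CharacterDefinition, attr: Attribute,
              style: DescriptionStyle) -> str:
    if char.kind is CharacterKind.NUMERIC:
        lo, hi = attr.range  # type: ignore[misc]
        value = _fmt_num(lo) if lo == hi else f"{_fmt_num(lo)}–{_fmt_num(hi)}"
        body = f"{char.label} {value}"
        if char.unit:
            body += f" {char.unit}"
    else:
        states = style.polymorphism_joiner.join(
            char.state_label(s) for s in sorted(attr.states))
        body = f"{char.label} {states}"
    if style.include_comments and attr.comment:
        body += f" ({attr.comment})"
    return body


def describe_taxon(dataset: Dataset, taxon: str,
                   style: DescriptionStyle | None = None) -> str:
    """Render one taxon; raises a lookup error for unknown names."""
    style = style or DescriptionStyle()
    record = dataset.taxon(taxon)

    # section order follows first appearance in the character list
    sections: list[str] = []
    for c in dataset.characters:
        if c.section not in sections:
            sections.append(c.section)

    parts: list[str] = []
    for section in sections:
        sentences = []
        for c in dataset.characters:
            if c.section != section:
                continue
            attr = record.attribute(c.number)
            if not attr.is_recorded:
                continue
            sentences.append(_sentence(c, attr, style))
        if not sentences:
            continue
        block = style.sentence_terminator.join(sentences).rstrip() + "."
        if style.section_headings and section:
            heading = f"**{section}.** " if style.markdown else f"{section}. -- "
            block = heading + block
        parts.append(block)
    return "\n\n".join(parts)


def describe_dataset(dataset: Dataset,
                     style: DescriptionStyle | None = None) -> dict[str, str]:
    """Descriptions for every taxon, keyed and ordered by taxon name."""
    return {name: describe_taxon(dataset, name, style)
            for name in sorted(dataset.taxon_names)}
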