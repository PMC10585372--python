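"""Canonical JSON serialization (versioned; schema is the Dataset.to_json
structure documented in the README)."""

from __future__ import annotations

import json
from pathlib import Path

from ..model import Dataset

__all__ = ["load_json", "loads_json", "dump_json", "dumps_json"]


def dumps_json(dataset: Dataset) -> str:
    """Deterministic canonical serialization (sorted cells, stable keys)."""
    return json.dumps(dataset.to_json(), indent=1, ensure_ascii=False) + "\n"


def loads_json(text: str) -> Dataset:
    return Dataset.from_json(json.loads(text))


def dump_json(dataset: Dataset, path: str | Path) -> None:
    Path(path).write_text(dumps_json(dataset), encoding="utf-8")


def load_json(path: str | Path) -> Dataset:
    return loads_json(Path(path).read_text(encoding="utf-8"))
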