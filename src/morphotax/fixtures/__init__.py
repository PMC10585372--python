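"""Packaged fixtures: the Nereididae genus matrix, the printed key to the
genera, and the per-genus printed diagnoses, all transcribed to canonical
JSON.  Loaders verify file checksums before parsing."""

from __future__ import annotations

import hashlib
import json
from importlib import resources

from ..model import Dataset

__all__ = [
    "FixtureIntegrityError",
    "load_nereididae_genera",
    "load_printed_key",
    "load_printed_diagnoses",
    "fixture_names",
]


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


def _data_dir():
    return resources.files(__name__) / "data"


def _read(name: str) -> dict:
    blob = (_data_dir() / name).read_bytes()
    sums = json.loads((_data_dir() / "checksums.json").read_text())
    expected = sums.get(name)
    actual = hashlib.sha256(blob).hexdigest()
    if expected is None or actual != expected:
        raise FixtureIntegrityError(
            f"fixture {name!r}: checksum {actual[:12]}... does not match "
            f"recorded {str(expected)[:12]}...")
    return json.loads(blob.decode("utf-8"))


def load_nereididae_genera() -> Dataset:
    """The 45-genus x 186-character matrix transcribed from the source
    descriptions (146 multistate + 40 numeric characters)."""
    return Dataset.from_json(_read("nereididae_genera.json"))


def load_printed_key() -> dict:
    """The printed 49-couplet key, encoded verbatim (including its known
    couplet 18/19 cross-reference anomaly).  Returns the raw JSON object;
    use :func:`morphotax.keys.Key.from_json` to get a typed key."""
    return _read("nereididae_key.json")


def load_printed_diagnoses() -> dict:
    """Per-genus printed minimal/secondary diagnosis character sets plus the
    documented curation issues."""
    return _read("nereididae_diagnoses.json")


def fixture_names() -> list[str]:
    return ["nereididae-genera"]
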