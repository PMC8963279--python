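"""Reusable payload readers for plugin parsers: TSV, CSV and JSON-lines.

A plugin's ``parser.py`` receives the dump folder path and must lazily yield
raw document trees.  These helpers cover the common flat-file cases; tabular
readers perform no type coercion unless the caller supplies per-column
converters (values otherwise stay strings).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Callable, Iterator, Mapping


def _payload_files(folder: str | Path, *suffixes: str) -> list[Path]:
    folder = Path(folder)
    return sorted(
        p
        for p in folder.rglob("*")
        if p.is_file() and p.suffix in suffixes and p.name != "release.json"
    )


def _rows(
    path: Path, delimiter: str, types: Mapping[str, Callable[[str], Any]] | None
) -> Iterator[dict]:
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter=delimiter):
            doc: dict[str, Any] = {}
            for key, value in row.items():
                if key is None or value is None or value == "":
                    continue
                if types and key in types:
                    doc[key] = types[key](value)
                else:
                    doc[key] = value
            yield doc


def parse_tsv(
    folder: str | Path, types: Mapping[str, Callable[[str], Any]] | None = None
) -> Iterator[dict]:
    """Yield one document per row of every ``.tsv`` file in the dump folder."""
    for path in _payload_files(folder, ".tsv"):
        yield from _rows(path, "\t", types)


def parse_csv(
    folder: str | Path, types: Mapping[str, Callable[[str], Any]] | None = None
) -> Iterator[dict]:
    """Yield one document per row of every ``.csv`` file in the dump folder."""
    for path in _payload_files(folder, ".csv"):
        yield from _rows(path, ",", types)


def parse_jsonl(folder: str | Path) -> Iterator[dict]:
    """Yield one document per line of every ``.jsonl``/``.ndjson`` file."""
    for path in _payload_files(folder, ".jsonl", ".ndjson"):
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                if line.strip():
                    yield json.loads(line)
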