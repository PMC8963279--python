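"""Per-source document stores.

A store holds validated annotation documents under a logical namespace
``(source, release)``.  Within one namespace ``_id`` is unique (last write
wins) and iteration order is ascending ``_id``.  Two reference backends are
provided: in-memory, and JSON-lines on disk (one document per line, UTF-8,
sorted by ``_id``), both satisfying the same contract.
"""

from __future__ import annotations

import json
import os
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Iterator


class DocumentStore(ABC):
    """Backend contract for the upload stage."""

    @abstractmethod
    def replace(self, source: str, release: str, docs: dict[str, dict]) -> None:
        """Atomically replace the ``(source, release)`` namespace wholesale."""

    @abstractmethod
    def iter_docs(self, source: str, release: str) -> Iterator[dict]:
        """Iterate documents in ascending ``_id`` order."""

    @abstractmethod
    def releases(self, source: str) -> list[str]:
        """Release values with stored documents, ascending."""

    @abstractmethod
    def count(self, source: str, release: str) -> int:
        ...

    def has(self, source: str, release: str) -> bool:
        return release in self.releases(source)

    def latest(self, source: str) -> str | None:
        releases = self.releases(source)
        return releases[-1] if releases else None

    def ids(self, source: str, release: str) -> set[str]:
        return {doc["_id"] for doc in self.iter_docs(source, release)}


class MemoryStore(DocumentStore):
    def __init__(self) -> None:
        self._data: dict[tuple[str, str], dict[str, dict]] = {}

    def replace(self, source: str, release: str, docs: dict[str, dict]) -> None:
        self._data[(source, release)] = dict(sorted(docs.items()))

    def iter_docs(self, source: str, release: str) -> Iterator[dict]:
        namespace = self._data.get((source, release), {})
        for _id in sorted(namespace):
            yield namespace[_id]

    def releases(self, source: str) -> list[str]:
        return sorted(rel for (src, rel) in self._data if src == source)

    def count(self, source: str, release: str) -> int:
        return len(self._data.get((source, release), {}))


class JsonLinesStore(DocumentStore):
    """On-disk store: ``<root>/store/<source>/<release>.jsonl``, sorted by ``_id``."""

    def __init__(self, data_root: str | Path):
        self.root = Path(data_root) / "store"

    def _path(self, source: str, release: str) -> Path:
        return self.root / source / f"{release}.jsonl"

    def replace(self, source: str, release: str, docs: dict[str, dict]) -> None:
        path = self._path(source, release)
        path.parent.mkdir(parents=True, exist_ok=True)
        temp = path.with_suffix(".jsonl.tmp")
        with open(temp, "w", encoding="utf-8") as handle:
            for _id in sorted(docs):
                handle.write(json.dumps(docs[_id], ensure_ascii=False, sort_keys=True))
                handle.write("\n")
        os.replace(temp, path)

    def iter_docs(self, source: str, release: str) -> Iterator[dict]:
        path = self._path(source, release)
        if not path.is_file():
            return
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                if line.strip():
                    yield json.loads(line)

    def releases(self, source: str) -> list[str]:
        source_dir = self.root / source
        if not source_dir.is_dir():
            return []
        return sorted(p.stem for p in source_dir.glob("*.jsonl"))

    def count(self, source: str, release: str) -> int:
        return sum(1 for _ in self.iter_docs(source, release))
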