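"""Inspection: profile every field path's observed types across a corpus and
derive a typed index mapping automatically.

Paths are dotted; lists are transparent (they flag the profile but do not
extend the path), mirroring search-engine array semantics.  The mapping
decides queryability: strings become exact-match ``keyword`` fields (numeric
strings are never promoted to numbers), pure integer paths become
``integer``, any int/float mix becomes ``float``, and a path observed as
both subtree and scalar is a conflict — excluded from the mapping with a
reason, so it remains stored but unqueryable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .documents import BOOLEAN, FLOAT, INTEGER, STRING, SUBTREE, iter_paths, scalar_type

CONFLICT = "conflict"
SCALAR_TYPES = (STRING, INTEGER, FLOAT, BOOLEAN)
#: Mapped types a query may touch (``object`` paths are structural only).
QUERYABLE_TYPES = ("keyword", "integer", "float", "boolean")
NUMERIC_TYPES = ("integer", "float")


@dataclass
class TypeProfile:
    path: str
    observed: dict[str, int] = field(default_factory=dict)  # type label -> occurrences
    in_list: bool = False
    doc_count: int = 0
    examples: list = field(default_factory=list)  # up to 3 distinct values

    def observe(self, label: str, value: object, in_list: bool) -> None:
        self.observed[label] = self.observed.get(label, 0) + 1
        self.in_list = self.in_list or in_list
        if (
            label != SUBTREE
            and len(self.examples) < 3
            and all(value != seen for seen in self.examples)
        ):
            self.examples.append(value)


@dataclass
class InspectionReport:
    profiles: dict[str, TypeProfile] = field(default_factory=dict)
    total_documents: int = 0

    @property
    def conflict_paths(self) -> list[str]:
        return sorted(
            path
            for path, profile in self.profiles.items()
            if SUBTREE in profile.observed
            and any(t in profile.observed for t in SCALAR_TYPES)
        )

    def paths(self) -> list[str]:
        return sorted(self.profiles)


def inspect_documents(docs: Iterable[dict]) -> InspectionReport:
    """Profile every field path of a document stream.

    Streaming: memory is linear in the number of distinct paths, not in the
    corpus size.  ``_id`` is excluded.  An empty list carries no type
    evidence, so a path whose only value is ``[]`` is not reported.
    """
    report = InspectionReport()
    for doc in docs:
        report.total_documents += 1
        seen_in_doc: set[str] = set()
        for path, value, in_list in iter_paths(doc):
            profile = report.profiles.get(path)
            if profile is None:
                profile = report.profiles[path] = TypeProfile(path=path)
            if isinstance(value, dict):
                profile.observe(SUBTREE, value, in_list)
            else:
                label = scalar_type(value)
                if label is not None:
                    profile.observe(label, value, in_list)
            if path not in seen_in_doc:
                seen_in_doc.add(path)
                profile.doc_count += 1
    return report


def join_types(a: Iterable[str], b: Iterable[str] = ()) -> str:
    """Join two observed-type sets into one mapped type on the type lattice.

    ``{integer} -> integer``; ``{integer, float} -> float``; any set with a
    string (and no subtree) ``-> keyword``; ``{boolean} -> boolean`` but
    boolean mixed with anything ``-> keyword``; ``{subtree} -> object``;
    subtree mixed with a scalar ``-> conflict``.  Commutative, associative
    and idempotent by construction (classification of the set union).
    """
    observed = frozenset(a) | frozenset(b)
    if not observed:
        raise ValueError("cannot join empty type sets")
    if SUBTREE in observed:
        return "object" if observed == {SUBTREE} else CONFLICT
    if STRING in observed:
        return "keyword"
    if BOOLEAN in observed:
        return "boolean" if observed == {BOOLEAN} else "keyword"
    if FLOAT in observed:
        return "float"
    return "integer"


@dataclass
class IndexMapping:
    """Typed declaration of which field paths are indexed, and as what.

    Fields outside the mapping (including conflict paths and everything
    beneath them) are stored with the documents but cannot be queried.
    """

    types: dict[str, str] = field(default_factory=dict)  # path -> mapped type
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (path, reason)

    def queryable_paths(self) -> list[str]:
        return sorted(p for p, t in self.types.items() if t in QUERYABLE_TYPES)

    def keyword_paths(self) -> list[str]:
        return sorted(p for p, t in self.types.items() if t == "keyword")

    def type_of(self, path: str) -> Optional[str]:
        return self.types.get(path)

    def to_es_dict(self) -> dict:
        """Serialize to the Elasticsearch-7 ``properties`` dialect."""
        root: dict = {"properties": {}}
        for path in sorted(self.types):
            mapped = self.types[path]
            node = root
            parts = path.split(".")
            for part in parts[:-1]:
                node = node["properties"].setdefault(part, {"properties": {}})
            leaf = parts[-1]
            if mapped == "object":
                node["properties"].setdefault(leaf, {"properties": {}})
            else:
                node["properties"][leaf] = {"type": mapped}
        return root

    def flat(self) -> dict[str, dict]:
        """Flattened ``path -> {"type": ...}`` view (for /metadata/fields)."""
        return {
            path: {"type": mapped}
            for path, mapped in sorted(self.types.items())
            if mapped in QUERYABLE_TYPES
        }

    def save(self, path: str | Path) -> None:
        payload = {
            "mapping": self.to_es_dict(),
            "flat": {p: t for p, t in sorted(self.types.items())},
            "excluded": [{"path": p, "reason": r} for p, r in self.excluded],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "IndexMapping":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if "flat" in payload:
            types = dict(payload["flat"])
            excluded = [(e["path"], e["reason"]) for e in payload.get("excluded", [])]
            return cls(types=types, excluded=excluded)
        # plain Elasticsearch dialect (e.g. a hand-edited mapping file)
        types: dict[str, str] = {}

        def walk(node: dict, prefix: str) -> None:
            for key, value in node.get("properties", {}).items():
                path = f"{prefix}.{key}" if prefix else key
                if "type" in value:
                    types[path] = value["type"]
                if "properties" in value:
                    types.setdefault(path, "object")
                    walk(value, path)

        walk(payload, "")
        return cls(types=types)


def generate_mapping(report: InspectionReport) -> IndexMapping:
    """Derive a typed mapping from an inspection report.

    Non-conflict paths are mapped via the type lattice; a conflict path is
    excluded with its reason, and nothing beneath it is mapped (it is covered
    by the excluded ancestor).
    """
    mapping = IndexMapping()
    conflicts = set(report.conflict_paths)
    for path in sorted(report.profiles):
        if any(path == c or path.startswith(c + ".") for c in conflicts):
            if path in conflicts:
                mapping.excluded.append((path, "object/scalar conflict"))
            continue
        mapping.types[path] = join_types(report.profiles[path].observed)
    return mapping
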