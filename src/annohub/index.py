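"""Embedded inverted index over a merged build, honoring the index mapping.

Only mapped paths are queryable; every stored document remains retrievable
in full by ``_id``, unmapped fields included — the indexed-versus-stored
distinction is the core contract.  Keyword terms are normalized to
lowercase at index time and matched case-insensitively exact (or by prefix
for wildcards).  Ranking is fully deterministic: descending per-document
match count across queried paths, ties broken by ascending ``_id``.
"""

from __future__ import annotations

import bisect
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .documents import values_at
from .errors import BuildError, UnqueryableFieldError
from .inspection import NUMERIC_TYPES, IndexMapping
from .merge import BuildResult, load_build
from .queryast import And, FieldTerm, Node, Or, Range, Term, Wildcard


class _NotFound:
    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_FOUND"


NOT_FOUND = _NotFound()

DEFAULT_SIZE = 10
MAX_SIZE = 1000


def normalize_term(value: object) -> str:
    """Canonical lowercase term form of a scalar (booleans become true/false)."""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value).lower()


@dataclass
class QueryResult:
    total: int
    hits: list[dict]
    from_: int
    size: int


@dataclass
class Index:
    """In-memory inverted index plus full document store by ``_id``."""

    mapping: IndexMapping
    docs: dict[str, dict] = field(default_factory=dict)
    # keyword path -> lowercase term -> set of ids
    terms: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    # numeric path -> sorted list of (value, id)
    numbers: dict[str, list[tuple[float, str]]] = field(default_factory=dict)
    skipped_values: int = 0  # values typed contrary to the mapping

    @property
    def total_documents(self) -> int:
        return len(self.docs)


def build_index(build: BuildResult, mapping: IndexMapping) -> Index:
    """Index every mapped path of every merged document.

    List values index each element.  A value typed contrary to the mapping
    (e.g. a string where an integer is mapped) leaves the document stored but
    skips that value from the inverted structures, counted in
    ``skipped_values``.
    """
    index = Index(mapping=mapping)
    for doc in build.merged:
        _id = doc["_id"]
        index.docs[_id] = doc
        for path in mapping.queryable_paths():
            mapped = mapping.types[path]
            for value in values_at(doc, path):
                if mapped == "keyword":
                    index.terms.setdefault(path, {}).setdefault(
                        normalize_term(value), set()
                    ).add(_id)
                elif mapped in NUMERIC_TYPES:
                    if isinstance(value, bool) or not isinstance(value, (int, float)):
                        index.skipped_values += 1
                        continue
                    index.numbers.setdefault(path, []).append((float(value), _id))
                elif mapped == "boolean":
                    if not isinstance(value, bool):
                        index.skipped_values += 1
                        continue
                    index.terms.setdefault(path, {}).setdefault(
                        normalize_term(value), set()
                    ).add(_id)
    for entries in index.numbers.values():
        entries.sort()
    # ensure every queryable path has an entry so lookups distinguish
    # "no match" from "unqueryable"
    for path in mapping.queryable_paths():
        if mapping.types[path] in NUMERIC_TYPES:
            index.numbers.setdefault(path, [])
        else:
            index.terms.setdefault(path, {})
    return index


def _range_ids(index: Index, node: Range) -> set[str]:
    entries = index.numbers[node.path]
    values = [v for v, _id in entries]
    if node.op == ">":
        lo = bisect.bisect_right(values, node.number)
        selected = entries[lo:]
    elif node.op == ">=":
        lo = bisect.bisect_left(values, node.number)
        selected = entries[lo:]
    elif node.op == "<":
        hi = bisect.bisect_left(values, node.number)
        selected = entries[:hi]
    else:  # <=
        hi = bisect.bisect_right(values, node.number)
        selected = entries[:hi]
    return {_id for _v, _id in selected}


def _check_queryable(index: Index, path: str, *, numeric: bool = False) -> str:
    mapped = index.mapping.type_of(path)
    if mapped is None or mapped not in ("keyword", "integer", "float", "boolean"):
        raise UnqueryableFieldError(path)
    if numeric and mapped not in NUMERIC_TYPES:
        raise UnqueryableFieldError(path, reason=f"mapped as {mapped}, not numeric")
    return mapped


def _leaf_counts(index: Index, node: Node) -> dict[str, int]:
    """Per-document match count for one leaf predicate."""
    counts: dict[str, int] = {}
    if isinstance(node, Term):
        term = node.value.lower()
        for path in index.mapping.keyword_paths():
            for _id in index.terms.get(path, {}).get(term, ()):
                counts[_id] = counts.get(_id, 0) + 1
        return counts
    if isinstance(node, FieldTerm):
        mapped = _check_queryable(index, node.path)
        if mapped in NUMERIC_TYPES:
            try:
                number = float(node.value)
            except ValueError:
                raise UnqueryableFieldError(
                    node.path, reason=f"non-numeric value {node.value!r} on a numeric field"
                ) from None
            entries = index.numbers[node.path]
            values = [v for v, _id in entries]
            lo = bisect.bisect_left(values, number)
            hi = bisect.bisect_right(values, number)
            return {_id: 1 for _v, _id in entries[lo:hi]}
        ids = index.terms.get(node.path, {}).get(node.value.lower(), set())
        return {_id: 1 for _id in ids}
    if isinstance(node, Wildcard):
        prefix = node.prefix.lower()
        if node.path is None:
            paths = index.mapping.keyword_paths()
        else:
            mapped = _check_queryable(index, node.path)
            if mapped not in ("keyword", "boolean"):
                raise UnqueryableFieldError(
                    node.path, reason=f"prefix match on {mapped} field"
                )
            paths = [node.path]
        for path in paths:
            for term, ids in index.terms.get(path, {}).items():
                if term.startswith(prefix):
                    for _id in ids:
                        counts[_id] = counts.get(_id, 0) + 1
        return counts
    if isinstance(node, Range):
        _check_queryable(index, node.path, numeric=True)
        return {_id: 1 for _id in _range_ids(index, node)}
    raise TypeError(f"not a leaf node: {node!r}")  # pragma: no cover


def _evaluate(index: Index, node: Node) -> dict[str, int]:
    """Evaluate a query tree to ``id -> match count`` (the ranking signal)."""
    if isinstance(node, And):
        child_counts = [_evaluate(index, child) for child in node.children]
        surviving = set(child_counts[0])
        for counts in child_counts[1:]:
            surviving &= set(counts)
        return {
            _id: sum(counts.get(_id, 0) for counts in child_counts)
            for _id in surviving
        }
    if isinstance(node, Or):
        merged: dict[str, int] = {}
        for child in node.children:
            for _id, count in _evaluate(index, child).items():
                merged[_id] = merged.get(_id, 0) + count
        return merged
    return _leaf_counts(index, node)


def execute_query(
    index: Index,
    ast: Node,
    from_: int = 0,
    size: int = DEFAULT_SIZE,
    fields: Optional[list[str] | str] = None,
) -> QueryResult:
    """Run a parsed query: match, rank, paginate, project.

    ``total`` is independent of pagination; ``size=0`` gives a count-only
    result.  Rank order is descending match count, then ascending ``_id`` —
    identical inputs always produce identical results.
    """
    if from_ < 0:
        raise ValueError("from must be >= 0")
    if size < 0:
        raise ValueError("size must be >= 0")
    if size > MAX_SIZE:
        raise ValueError(f"size exceeds the cap of {MAX_SIZE}")
    counts = _evaluate(index, ast)
    ranked = sorted(counts, key=lambda _id: (-counts[_id], _id))
    page = ranked[from_ : from_ + size]
    hits = [project_fields(index.docs[_id], fields) for _id in page]
    return QueryResult(total=len(ranked), hits=hits, from_=from_, size=size)


def project_fields(doc: dict, fields: Optional[list[str] | str]) -> dict:
    """Project a document onto the requested dotted paths.

    ``_id`` is always included; a requested path brings its whole subtree;
    missing paths contribute nothing; ``"all"`` (or None) returns the full
    document.
    """
    if fields is None or fields == "all" or fields == ["all"]:
        return doc
    projected: dict = {"_id": doc["_id"]}
    for path in fields:
        parts = path.split(".")
        node = doc
        for part in parts[:-1]:
            if not isinstance(node, dict) or part not in node:
                node = None
                break
            node = node[part]
        if not isinstance(node, dict) or parts[-1] not in node:
            continue
        target = projected
        for part in parts[:-1]:
            target = target.setdefault(part, {})
        target[parts[-1]] = node[parts[-1]]
    return projected


def get_by_id(index: Index, _id: str):
    """Byte-exact stored document (unmapped fields included) or NOT_FOUND."""
    return index.docs.get(_id, NOT_FOUND)


def save_index(index: Index, build_folder: str | Path) -> Path:
    """Persist the index beside its build (format private to this backend)."""
    target = Path(build_folder) / "index"
    if target.exists():
        shutil.rmtree(target)
    target.mkdir(parents=True)
    index.mapping.save(target / "mapping.json")
    (target / "index.json").write_text(
        json.dumps(
            {"documents": index.total_documents, "skipped_values": index.skipped_values}
        ),
        encoding="utf-8",
    )
    return target


def load_index(data_root: str | Path, build_version: str) -> tuple[Index, BuildResult]:
    """Load a persisted build + index pair, rebuilding the inverted structures."""
    build = load_build(data_root, build_version)
    assert build.folder is not None
    mapping_path = build.folder / "index" / "mapping.json"
    if not mapping_path.is_file():
        raise BuildError(f"build {build_version!r} has not been indexed")
    mapping = IndexMapping.load(mapping_path)
    return build_index(build, mapping), build
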