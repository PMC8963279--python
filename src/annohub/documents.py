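"""Annotation documents: validation and tree traversal helpers.

An annotation document is a JSON-style tree keyed by a unique string ``_id``.
Leaves are strings, integers, finite floats or booleans; inner nodes are
key/value subtrees or lists.  Field keys may not contain ``.`` (reserved for
path notation) nor begin with ``$`` (document-store operator prefix), so
documents remain drop-in compatible with common document stores.
"""

from __future__ import annotations

import math
from typing import Any, Iterator

MAX_ID_LENGTH = 512

#: Observed-type labels used by the inspector and validator.
STRING, INTEGER, FLOAT, BOOLEAN, SUBTREE = (
    "string",
    "integer",
    "float",
    "boolean",
    "subtree",
)


def scalar_type(value: Any) -> str | None:
    """Return the observed-type label of a scalar leaf, or None if not a scalar."""
    # bool is a subclass of int: test it first
    if isinstance(value, bool):
        return BOOLEAN
    if isinstance(value, int):
        return INTEGER
    if isinstance(value, float):
        return FLOAT
    if isinstance(value, str):
        return STRING
    return None


def validate_document(raw: Any) -> list[str]:
    """Validate a raw tree against the document invariants.

    Returns the full list of violations (empty when valid); never stops at
    the first problem.  No coercion is performed: an integer-valued float
    stays a float.
    """
    violations: list[str] = []
    if not isinstance(raw, dict):
        return [f"document must be a key/value tree, got {type(raw).__name__}"]

    _id = raw.get("_id")
    if "_id" not in raw:
        violations.append("missing `_id`")
    elif not isinstance(_id, str):
        violations.append(f"`_id` must be a string, got {type(_id).__name__}")
    elif not _id:
        violations.append("`_id` is empty")
    elif _id != _id.strip():
        violations.append("`_id` has leading/trailing whitespace")
    elif len(_id) > MAX_ID_LENGTH:
        violations.append(f"`_id` longer than {MAX_ID_LENGTH} characters")

    def walk(node: Any, path: str) -> None:
        if isinstance(node, dict):
            for key, value in node.items():
                if not isinstance(key, str) or not key:
                    violations.append(f"non-string or empty key at {path or '<root>'}")
                    continue
                if "." in key:
                    violations.append(f"key contains '.': {key!r} at {path or '<root>'}")
                    continue
                if key.startswith("$"):
                    violations.append(f"key begins with '$': {key!r} at {path or '<root>'}")
                    continue
                if path == "" and key == "_id":
                    continue
                walk(value, f"{path}.{key}" if path else key)
        elif isinstance(node, list):
            for item in node:
                walk(item, path)
        else:
            kind = scalar_type(node)
            if kind is None:
                violations.append(
                    f"unsupported leaf type {type(node).__name__} at {path or '<root>'}"
                )
            elif kind == FLOAT and not math.isfinite(node):
                violations.append(f"non-finite float at {path or '<root>'}")

    walk(raw, "")
    return violations


def iter_paths(body: dict, *, _prefix: str = "") -> Iterator[tuple[str, Any, bool]]:
    """Yield ``(dotted_path, value, in_list)`` for every node below the root.

    Lists are transparent: they do not extend the path, but everything under
    them is flagged ``in_list=True``.  Subtrees are yielded (with the dict as
    value) before their children.  The top-level ``_id`` key is skipped.
    """

    def walk(node: Any, prefix: str, in_list: bool) -> Iterator[tuple[str, Any, bool]]:
        if isinstance(node, dict):
            for key, value in node.items():
                if prefix == "" and key == "_id":
                    continue
                path = f"{prefix}.{key}" if prefix else key
                if isinstance(value, dict):
                    yield path, value, in_list
                    yield from walk(value, path, in_list)
                elif isinstance(value, list):
                    yield from walk_list(value, path)
                else:
                    yield path, value, in_list
        # lists handled by walk_list

    def walk_list(items: list, path: str) -> Iterator[tuple[str, Any, bool]]:
        for item in items:
            if isinstance(item, dict):
                yield path, item, True
                yield from walk(item, path, True)
            elif isinstance(item, list):
                yield from walk_list(item, path)
            else:
                yield path, item, True

    yield from walk(body, _prefix, False)


def values_at(node: Any, path: str) -> list[Any]:
    """Collect every scalar value reachable at a dotted ``path``.

    Lists at any depth are traversed transparently, mirroring search-engine
    array semantics: ``values_at({"a": [{"b": 1}, {"b": 2}]}, "a.b") == [1, 2]``.
    """
    parts = path.split(".") if path else []
    out: list[Any] = []

    def walk(current: Any, remaining: list[str]) -> None:
        if isinstance(current, list):
            for item in current:
                walk(item, remaining)
            return
        if not remaining:
            if scalar_type(current) is not None:
                out.append(current)
            return
        if isinstance(current, dict):
            head, *rest = remaining
            if head in current:
                walk(current[head], rest)

    walk(node, parts)
    return out
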