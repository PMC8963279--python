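"""Deterministic synthetic data sources with known ground truth.

Every pipeline stage is testable offline: this module writes complete data
plugins (payload + ``manifest.json`` + ``parser.py``) with controlled
identifier overlap, nesting, list fields, mixed-type fields and injected
object/scalar conflicts, and returns truth tables computed *during*
generation — never by re-parsing the output.

The canonical tiny corpus FIX1 (sources ``alpha`` and ``beta`` sharing gene
``g1``) is available as a named preset; identifiers follow the scheme
``g<zero-padded integer>`` so ordering assertions stay readable.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional

from .documents import scalar_type, values_at
from .errors import UnqueryableFieldError
from .inspection import NUMERIC_TYPES, IndexMapping
from .queryast import And, FieldTerm, Node, Or, Range, Term, Wildcard

_SYMBOLS = [
    "CDK2", "TP53", "BRCA1", "EGFR", "MYC", "KRAS", "PTEN", "RB1",
    "AKT1", "BRAF", "NOTCH1", "JAK2", "STAT3", "MTOR", "VEGFA", "FGFR2",
]
_PATHWAYS = ["cell_cycle", "dna_repair", "apoptosis", "signaling", "metabolism"]
_TAXIDS = [9606, 10090, 10116, 7227]


@dataclass
class SourceRecipe:
    """Controls one synthetic source's payload."""

    name: str
    fmt: str = "jsonl"  # tsv | csv | jsonl
    n_docs: int = 10
    id_offset: int = 0  # first identifier index; overlap = overlapping index ranges
    nested_depth: int = 0  # extra subtree nesting (<= 3)
    with_list_field: bool = False
    mixed_type_probability: float = 0.0  # chance a doc's score is float vs int
    inject_conflict: bool = False  # field observed as both scalar and subtree
    schedule: Optional[str] = None
    priority: int = 100


@dataclass
class FixtureSpec:
    seed: int
    sources: list[SourceRecipe]


@dataclass
class FixtureTruth:
    """Ground truth computed by construction during generation."""

    ids_per_source: dict[str, set[str]] = field(default_factory=dict)
    docs_per_source: dict[str, dict[str, dict]] = field(default_factory=dict)
    # namespaced path -> set of observed type labels over the merged corpus
    path_types: dict[str, set[str]] = field(default_factory=dict)
    list_paths: set[str] = field(default_factory=set)
    conflict_paths: set[str] = field(default_factory=set)
    plugin_dirs: dict[str, Path] = field(default_factory=dict)

    @property
    def union_ids(self) -> set[str]:
        return set().union(*self.ids_per_source.values()) if self.ids_per_source else set()

    def intersection(self, a: str, b: str) -> set[str]:
        return self.ids_per_source[a] & self.ids_per_source[b]

    def merged_ids(self, roots: Iterable[str]) -> set[str]:
        roots = list(roots)
        if not roots:
            return self.union_ids
        gate = set().union(*(self.ids_per_source[r] for r in roots))
        return self.union_ids & gate


def _gene_id(index: int) -> str:
    return f"g{index:04d}"


def _record_paths(truth: FixtureTruth, source: str, body: dict) -> None:
    """Record namespaced path observations for one document body (by construction)."""

    def walk(node: Any, prefix: str, in_list: bool) -> None:
        if isinstance(node, dict):
            for key, value in node.items():
                path = f"{prefix}.{key}"
                if isinstance(value, dict):
                    truth.path_types.setdefault(path, set()).add("subtree")
                    if in_list:
                        truth.list_paths.add(path)
                    walk(value, path, in_list)
                elif isinstance(value, list):
                    for item in value:
                        if isinstance(item, dict):
                            truth.path_types.setdefault(path, set()).add("subtree")
                            truth.list_paths.add(path)
                            walk(item, path, True)
                        else:
                            label = scalar_type(item)
                            if label:
                                truth.path_types.setdefault(path, set()).add(label)
                                truth.list_paths.add(path)
                else:
                    label = scalar_type(value)
                    if label:
                        truth.path_types.setdefault(path, set()).add(label)
                        if in_list:
                            truth.list_paths.add(path)

    walk(body, source, False)


def _make_doc(recipe: SourceRecipe, rng: random.Random, ordinal: int, _id: str) -> dict:
    doc: dict[str, Any] = {"_id": _id}
    doc["symbol"] = rng.choice(_SYMBOLS)
    doc["taxid"] = rng.choice(_TAXIDS)
    if recipe.fmt in ("tsv", "csv"):
        doc["desc"] = f"synthetic gene {ordinal}"
        return doc
    if recipe.with_list_field:
        count = rng.randint(1, 3)
        doc["pathway"] = rng.sample(_PATHWAYS, count)
    if recipe.nested_depth > 0:
        node: dict[str, Any] = {"accession": f"ACC{rng.randint(1000, 9999)}"}
        for level in range(min(recipe.nested_depth, 3) - 1, 0, -1):
            node = {f"level{level}": node}
        doc["info"] = node
    if recipe.mixed_type_probability > 0:
        if rng.random() < recipe.mixed_type_probability:
            doc["score"] = round(rng.uniform(0, 10), 2)
        else:
            doc["score"] = rng.randint(0, 10)
    if recipe.inject_conflict:
        if ordinal % 2 == 0:
            doc["extra"] = "plain note"
        else:
            doc["extra"] = {"note": "structured"}
    return doc


def _write_payload(recipe: SourceRecipe, docs: list[dict], payload_dir: Path) -> Path:
    payload_dir.mkdir(parents=True, exist_ok=True)
    if recipe.fmt == "jsonl":
        path = payload_dir / f"{recipe.name}.jsonl"
        with open(path, "w", encoding="utf-8") as handle:
            for doc in docs:
                handle.write(json.dumps(doc, ensure_ascii=False, sort_keys=True))
                handle.write("\n")
        return path
    delimiter = "\t" if recipe.fmt == "tsv" else ","
    path = payload_dir / f"{recipe.name}.{recipe.fmt}"
    columns = ["_id", "symbol", "taxid", "desc"]
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write(delimiter.join(columns) + "\n")
        for doc in docs:
            handle.write(
                delimiter.join(str(doc.get(c, "")) for c in columns) + "\n"
            )
    return path


_PARSER_TEMPLATES = {
    "jsonl": (
        "from annohub.parsers import parse_jsonl\n\n\n"
        "def parse(folder):\n"
        "    yield from parse_jsonl(folder)\n"
    ),
    "tsv": (
        "from annohub.parsers import parse_tsv\n\n\n"
        "def parse(folder):\n"
        "    yield from parse_tsv(folder, types={'taxid': int})\n"
    ),
    "csv": (
        "from annohub.parsers import parse_csv\n\n\n"
        "def parse(folder):\n"
        "    yield from parse_csv(folder, types={'taxid': int})\n"
    ),
}


def _write_plugin(recipe: SourceRecipe, payload: Path, plugins_dir: Path) -> Path:
    plugin_dir = plugins_dir / recipe.name
    plugin_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "name": recipe.name,
        "location": payload.resolve().as_uri(),
        "parser_ref": "parser:parse",
        "priority": recipe.priority,
        "metadata": {"description": f"synthetic source {recipe.name}"},
    }
    if recipe.schedule:
        manifest["schedule"] = recipe.schedule
    (plugin_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    (plugin_dir / "parser.py").write_text(
        _PARSER_TEMPLATES[recipe.fmt], encoding="utf-8"
    )
    return plugin_dir


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureTruth:
    """Write every source's payload and plugin; return the truth tables.

    Deterministic: the same ``(seed, spec)`` produces byte-identical files.
    Each source draws from its own counter-derived stream, so adding a source
    never perturbs the others.
    """
    out_dir = Path(out_dir)
    truth = FixtureTruth()
    for index, recipe in enumerate(spec.sources):
        rng = random.Random((spec.seed * 1_000_003 + index * 7919) % (2**31))
        docs = []
        ids: set[str] = set()
        for ordinal in range(recipe.n_docs):
            _id = _gene_id(recipe.id_offset + ordinal)
            doc = _make_doc(recipe, rng, ordinal, _id)
            docs.append(doc)
            ids.add(_id)
            _record_paths(truth, recipe.name, {k: v for k, v in doc.items() if k != "_id"})
        payload = _write_payload(recipe, docs, out_dir / "payloads" / recipe.name)
        plugin_dir = _write_plugin(recipe, payload, out_dir / "plugins")
        truth.ids_per_source[recipe.name] = ids
        truth.docs_per_source[recipe.name] = {d["_id"]: d for d in docs}
        truth.plugin_dirs[recipe.name] = plugin_dir
        if recipe.inject_conflict and recipe.n_docs >= 2:
            truth.conflict_paths.add(f"{recipe.name}.extra")
    return truth


# --- the canonical tiny corpus ------------------------------------------------

FIX1_ALPHA_DOCS = {
    "g1": {"_id": "g1", "symbol": "CDK2", "taxid": 9606},
    "g2": {"_id": "g2", "symbol": "TP53", "taxid": 9606},
}
FIX1_BETA_DOCS = {
    "g1": {"_id": "g1", "pathway": ["cell_cycle", "dna_repair"]},
    "g3": {"_id": "g3", "pathway": ["apoptosis"]},
}


def generate_fix1(out_dir: str | Path) -> FixtureTruth:
    """Write the FIX1 preset: alpha (TSV, ids g1,g2) and beta (JSONL, ids g1,g3)."""
    out_dir = Path(out_dir)
    truth = FixtureTruth()

    alpha_docs = list(FIX1_ALPHA_DOCS.values())
    alpha_recipe = SourceRecipe(name="alpha", fmt="tsv")
    payload_dir = out_dir / "payloads" / "alpha"
    payload_dir.mkdir(parents=True, exist_ok=True)
    alpha_payload = payload_dir / "alpha.tsv"
    with open(alpha_payload, "w", encoding="utf-8") as handle:
        handle.write("_id\tsymbol\ttaxid\n")
        for doc in alpha_docs:
            handle.write(f"{doc['_id']}\t{doc['symbol']}\t{doc['taxid']}\n")
    truth.plugin_dirs["alpha"] = _write_plugin(alpha_recipe, alpha_payload, out_dir / "plugins")

    beta_docs = list(FIX1_BETA_DOCS.values())
    beta_recipe = SourceRecipe(name="beta", fmt="jsonl")
    beta_payload = _write_payload(beta_recipe, beta_docs, out_dir / "payloads" / "beta")
    truth.plugin_dirs["beta"] = _write_plugin(beta_recipe, beta_payload, out_dir / "plugins")

    truth.ids_per_source = {"alpha": {"g1", "g2"}, "beta": {"g1", "g3"}}
    truth.docs_per_source = {"alpha": dict(FIX1_ALPHA_DOCS), "beta": dict(FIX1_BETA_DOCS)}
    for source, docs in truth.docs_per_source.items():
        for doc in docs.values():
            _record_paths(truth, source, {k: v for k, v in doc.items() if k != "_id"})
    return truth


# --- in-memory corpora and random query trees ---------------------------------

def synthetic_corpus(rng: random.Random, n_docs: int) -> list[dict]:
    """Build a merged-style corpus directly in memory for query testing.

    Documents carry a mix of keyword, integer, float, boolean, list and
    nested fields, each present with some probability so paths differ across
    documents.  Ascending ``_id`` order, deterministic in ``rng``.
    """
    docs = []
    for ordinal in range(n_docs):
        doc: dict[str, Any] = {"_id": _gene_id(ordinal)}
        anno: dict[str, Any] = {"symbol": rng.choice(_SYMBOLS)}
        if rng.random() < 0.9:
            anno["taxid"] = rng.choice(_TAXIDS)
        if rng.random() < 0.7:
            anno["score"] = (
                round(rng.uniform(0, 10), 2) if rng.random() < 0.5 else rng.randint(0, 10)
            )
        if rng.random() < 0.5:
            anno["reviewed"] = rng.random() < 0.5
        doc["anno"] = anno
        if rng.random() < 0.6:
            doc["path"] = {"pathway": rng.sample(_PATHWAYS, rng.randint(1, 3))}
        if rng.random() < 0.4:
            doc["xref"] = {"info": {"accession": f"ACC{rng.randint(1000, 9999)}"}}
        docs.append(doc)
    return docs


def corpus_vocabulary(docs: Iterable[dict], mapping: IndexMapping) -> dict[str, list]:
    """Scalar values present per queryable path (so random queries can hit)."""
    vocabulary: dict[str, list] = {}
    for doc in docs:
        for path in mapping.queryable_paths():
            for value in values_at(doc, path):
                vocabulary.setdefault(path, []).append(value)
    return vocabulary


def random_ast(
    rng: random.Random,
    mapping: IndexMapping,
    vocabulary: dict[str, list],
    depth: int = 3,
) -> Node:
    """Draw a random query tree (depth <= ``depth``) over mapped paths.

    Leaf values are sampled from the corpus vocabulary most of the time, so
    generated queries match documents often enough to exercise ranking and
    set algebra rather than returning empty sets.
    """
    keyword_paths = mapping.keyword_paths()
    numeric_paths = [p for p, t in mapping.types.items() if t in NUMERIC_TYPES]

    def leaf() -> Node:
        choices = ["term", "fieldterm", "wildcard"]
        if numeric_paths:
            choices += ["range", "range"]
        kind = rng.choice(choices)
        if kind == "range":
            path = rng.choice(numeric_paths)
            op = rng.choice([">", ">=", "<", "<="])
            pool = [v for v in vocabulary.get(path, []) if isinstance(v, (int, float))]
            number = float(rng.choice(pool)) if pool and rng.random() < 0.8 else rng.uniform(0, 10)
            return Range(path=path, op=op, number=round(float(number), 2))
        if kind == "fieldterm":
            paths = mapping.queryable_paths()
            path = rng.choice(paths)
            mapped = mapping.types[path]
            pool = vocabulary.get(path, [])
            if pool and rng.random() < 0.8:
                value = rng.choice(pool)
                if isinstance(value, bool):
                    value = "true" if value else "false"
                return FieldTerm(path=path, value=str(value))
            if mapped in NUMERIC_TYPES:  # a fielded term on a numeric path must parse
                return FieldTerm(path=path, value=str(rng.randint(0, 9999)))
            if mapped == "boolean":
                return FieldTerm(path=path, value=rng.choice(["true", "false"]))
            return FieldTerm(path=path, value=rng.choice(_SYMBOLS))
        if kind == "wildcard":
            if keyword_paths and rng.random() < 0.6:
                path = rng.choice(keyword_paths)
                pool = [v for v in vocabulary.get(path, []) if isinstance(v, str)]
                word = rng.choice(pool) if pool else rng.choice(_SYMBOLS)
                return Wildcard(path=path, prefix=word[: rng.randint(1, max(1, len(word)))].lower())
            word = rng.choice(_SYMBOLS)
            return Wildcard(path=None, prefix=word[: rng.randint(1, 3)].lower())
        # bare term over all keyword paths
        pool = [v for values in vocabulary.values() for v in values if isinstance(v, str)]
        word = rng.choice(pool) if pool and rng.random() < 0.8 else rng.choice(_PATHWAYS)
        return Term(value=str(word).lower())

    def tree(level: int) -> Node:
        if level >= depth or rng.random() < 0.4:
            return leaf()
        children = tuple(tree(level + 1) for _ in range(rng.randint(2, 3)))
        return And(children) if rng.random() < 0.5 else Or(children)

    return tree(1)


# --- brute-force query referee ------------------------------------------------

def _doc_matches_leaf(doc: dict, node: Node, mapping: IndexMapping) -> int:
    """Match count of one leaf predicate against one document, by direct scan."""

    def keyword_values(path: str) -> list[str]:
        return [
            ("true" if v else "false") if isinstance(v, bool) else str(v).lower()
            for v in values_at(doc, path)
        ]

    if isinstance(node, Term):
        term = node.value.lower()
        return sum(term in keyword_values(p) for p in mapping.keyword_paths())
    if isinstance(node, Wildcard):
        prefix = node.prefix.lower()
        if node.path is None:
            paths = mapping.keyword_paths()
        else:
            mapped = mapping.type_of(node.path)
            if mapped not in ("keyword", "boolean"):
                raise UnqueryableFieldError(node.path)
            paths = [node.path]
        return sum(
            any(v.startswith(prefix) for v in keyword_values(p)) for p in paths
        )
    if isinstance(node, FieldTerm):
        mapped = mapping.type_of(node.path)
        if mapped not in ("keyword", "integer", "float", "boolean"):
            raise UnqueryableFieldError(node.path)
        if mapped in NUMERIC_TYPES:
            try:
                number = float(node.value)
            except ValueError:
                raise UnqueryableFieldError(node.path) from None
            return int(
                any(
                    not isinstance(v, bool)
                    and isinstance(v, (int, float))
                    and float(v) == number
                    for v in values_at(doc, node.path)
                )
            )
        return int(node.value.lower() in keyword_values(node.path))
    if isinstance(node, Range):
        mapped = mapping.type_of(node.path)
        if mapped not in NUMERIC_TYPES:
            raise UnqueryableFieldError(node.path)
        compare = {
            ">": lambda v: v > node.number,
            ">=": lambda v: v >= node.number,
            "<": lambda v: v < node.number,
            "<=": lambda v: v <= node.number,
        }[node.op]
        return int(
            any(
                not isinstance(v, bool) and isinstance(v, (int, float)) and compare(v)
                for v in values_at(doc, node.path)
            )
        )
    raise TypeError(f"not a leaf: {node!r}")  # pragma: no cover


def _doc_matches(doc: dict, node: Node, mapping: IndexMapping) -> bool:
    if isinstance(node, And):
        return all(_doc_matches(doc, child, mapping) for child in node.children)
    if isinstance(node, Or):
        return any(_doc_matches(doc, child, mapping) for child in node.children)
    return _doc_matches_leaf(doc, node, mapping) > 0


def oracle_query(docs: Iterable[dict], ast: Node, mapping: IndexMapping) -> set[str]:
    """Evaluate a query tree per document by recursive scan — no index.

    The independent referee for the query engine's oracle-equivalence
    property; it raises the same unqueryable-field errors, driven by the
    supplied mapping.
    """
    matching: set[str] = set()
    for doc in docs:
        if _doc_matches(doc, ast, mapping):
            matching.add(doc["_id"])
    return matching
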