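"""Inspector: path profiling, the type lattice, mapping generation."""

from __future__ import annotations

import itertools
import random

import pytest

from annohub import generate_mapping, inspect_documents, join_types
from annohub.documents import BOOLEAN, FLOAT, INTEGER, STRING, SUBTREE
from annohub.fixtures import synthetic_corpus
from annohub.inspection import CONFLICT

ALL_TYPES = [STRING, INTEGER, FLOAT, BOOLEAN, SUBTREE]


class TestInspectDocuments:
    def test_scalar_path_profiled(self):
        report = inspect_documents([{"_id": "g1", "alpha": {"taxid": 9606}}])
        profile = report.profiles["alpha.taxid"]
        assert set(profile.observed) == {INTEGER}
        assert profile.doc_count == 1

    def test_mixed_types_across_documents(self):
        report = inspect_documents(
            [{"_id": "g1", "x": 1}, {"_id": "g2", "x": "a"}]
        )
        assert set(report.profiles["x"].observed) == {INTEGER, STRING}

    def test_lists_are_transparent(self):
        report = inspect_documents([{"_id": "g1", "tags": ["a", "b"]}])
        profile = report.profiles["tags"]
        assert set(profile.observed) == {STRING}
        assert profile.in_list is True

    def test_id_excluded(self):
        report = inspect_documents([{"_id": "g1", "x": 1}])
        assert "_id" not in report.profiles

    def test_conflict_detected(self):
        report = inspect_documents(
            [{"_id": "g1", "extra": "note"}, {"_id": "g2", "extra": {"k": 1}}]
        )
        assert report.conflict_paths == ["extra"]

    def test_scalar_and_list_of_scalars_is_not_a_conflict(self):
        report = inspect_documents(
            [{"_id": "g1", "x": "a"}, {"_id": "g2", "x": ["b", "c"]}]
        )
        assert report.conflict_paths == []

    def test_empty_stream(self):
        report = inspect_documents([])
        assert report.total_documents == 0
        assert report.paths() == []

    def test_examples_capped_at_three_distinct(self):
        docs = [{"_id": f"g{i}", "x": f"v{i % 5}"} for i in range(10)]
        report = inspect_documents(docs)
        assert len(report.profiles["x"].examples) == 3


def enumerate_paths_brute_force(docs) -> set[str]:
    """Independent recursive enumeration of every path in a corpus."""
    paths: set[str] = set()

    def walk(node, prefix):
        if isinstance(node, dict):
            for key, value in node.items():
                if prefix == "" and key == "_id":
                    continue
                path = f"{prefix}.{key}" if prefix else key
                if isinstance(value, dict):
                    paths.add(path)
                    walk(value, path)
                elif isinstance(value, list):
                    walk_list(value, path)
                else:
                    paths.add(path)

    def walk_list(items, path):
        for item in items:
            if isinstance(item, dict):
                paths.add(path)
                walk(item, path)
            elif isinstance(item, list):
                walk_list(item, path)
            else:
                paths.add(path)

    for doc in docs:
        walk(doc, "")
    return paths


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_reported_paths_match_recursive_enumeration(self, seed):
        rng = random.Random(seed)
        docs = synthetic_corpus(rng, 100)
        report = inspect_documents(docs)
        assert set(report.paths()) == enumerate_paths_brute_force(docs)

    def test_stream_order_invariance(self):
        rng = random.Random(11)
        docs = synthetic_corpus(rng, 60)
        forward = inspect_documents(docs)
        backward = inspect_documents(list(reversed(docs)))
        assert forward.paths() == backward.paths()
        for path in forward.paths():
            a, b = forward.profiles[path], backward.profiles[path]
            assert a.observed == b.observed
            assert a.doc_count == b.doc_count
            assert a.in_list == b.in_list


def all_subsets():
    out = []
    for r in range(len(ALL_TYPES) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(ALL_TYPES, r))
    return out


class TestJoinTypes:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({INTEGER}, {INTEGER}, "integer"),
            ({INTEGER}, {FLOAT}, "float"),
            ({INTEGER}, {STRING}, "keyword"),
            ({BOOLEAN}, set(), "boolean"),
            ({BOOLEAN}, {INTEGER}, "keyword"),
            ({SUBTREE}, set(), "object"),
            ({SUBTREE}, {STRING}, CONFLICT),
        ],
    )
    def test_lattice_table(self, a, b, expected):
        assert join_types(a, b) == expected

    def test_lattice_laws_exhaustive(self):
        subsets = [s for s in all_subsets() if s]
        for a in subsets:
            assert join_types(a, a) == join_types(a)  # idempotent
            for b in subsets:
                assert join_types(a, b) == join_types(b, a)  # commutative
        # associativity via the underlying set union, over a sample of triples
        for a, b, c in itertools.islice(itertools.product(subsets, repeat=3), 0, None, 97):
            assert join_types(frozenset(a) | frozenset(b), c) == join_types(
                a, frozenset(b) | frozenset(c)
            )


class TestGenerateMapping:
    def test_fix1_style_corpus(self):
        docs = [
            {"_id": "g1", "alpha": {"symbol": "CDK2", "taxid": 9606},
             "beta": {"pathway": ["cell_cycle", "dna_repair"]}},
            {"_id": "g2", "alpha": {"symbol": "TP53", "taxid": 9606}},
        ]
        mapping = generate_mapping(inspect_documents(docs))
        assert mapping.types["alpha.symbol"] == "keyword"
        assert mapping.types["alpha.taxid"] == "integer"
        assert mapping.types["beta.pathway"] == "keyword"
        assert mapping.types["alpha"] == "object"

    def test_numeric_string_not_promoted(self):
        mapping = generate_mapping(
            inspect_documents([{"_id": "g1", "taxid": "9606"}])
        )
        assert mapping.types["taxid"] == "keyword"

    def test_empty_report_empty_mapping(self):
        mapping = generate_mapping(inspect_documents([]))
        assert mapping.types == {} and mapping.excluded == []

    def test_conflict_excluded_with_reason(self):
        docs = [
            {"_id": "g1", "extra": "note"},
            {"_id": "g2", "extra": {"inner": 1}},
        ]
        mapping = generate_mapping(inspect_documents(docs))
        assert mapping.excluded == [("extra", "object/scalar conflict")]
        assert "extra" not in mapping.types
        assert "extra.inner" not in mapping.types

    def test_soundness_every_leaf_mapped_or_under_exclusion(self):
        rng = random.Random(5)
        docs = synthetic_corpus(rng, 80)
        docs[0]["anno"]["weird"] = {"deep": True}
        docs[1]["anno"] = {"weird": "scalar", "symbol": "MYC"}
        report = inspect_documents(docs)
        mapping = generate_mapping(report)
        excluded = {p for p, _r in mapping.excluded}
        for path in report.paths():
            covered = (
                path in mapping.types
                or path in excluded
                or any(path.startswith(e + ".") for e in excluded)
            )
            assert covered, path
        for path in mapping.types:
            assert path in report.profiles  # mapped paths occur in >=1 document

    def test_es_dialect_serialization_round_trip(self, tmp_path):
        docs = [{"_id": "g1", "alpha": {"symbol": "CDK2", "taxid": 9606}}]
        mapping = generate_mapping(inspect_documents(docs))
        es = mapping.to_es_dict()
        assert es["properties"]["alpha"]["properties"]["symbol"] == {"type": "keyword"}
        mapping.save(tmp_path / "mapping.json")
        from annohub import IndexMapping

        loaded = IndexMapping.load(tmp_path / "mapping.json")
        assert loaded.types == mapping.types
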