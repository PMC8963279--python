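"""Query engine: grammar, execution vs the brute-force referee, pagination."""

from __future__ import annotations

import random

import pytest

from annohub import (
    NOT_FOUND,
    QueryParseError,
    UnqueryableFieldError,
    execute_query,
    get_by_id,
    parse_query,
    project_fields,
)
from annohub.fixtures import (
    corpus_vocabulary,
    oracle_query,
    random_ast,
    synthetic_corpus,
)
from annohub.queryast import And, FieldTerm, Or, Range, Term, Wildcard

from conftest import index_for


class TestParseQuery:
    @pytest.mark.parametrize(
        "q,expected",
        [
            ("alpha.symbol:CDK2", FieldTerm("alpha.symbol", "CDK2")),
            ("CDK2", Term("CDK2")),
            ("CDK2 OR TP53", Or((Term("CDK2"), Term("TP53")))),
            (
                "alpha.taxid:>9000 AND beta.pathway:cell_cycle",
                And((Range("alpha.taxid", ">", 9000.0), FieldTerm("beta.pathway", "cell_cycle"))),
            ),
            ("CDK2 TP53", And((Term("CDK2"), Term("TP53")))),  # implicit AND
            ("symbol:CDK*", Wildcard("symbol", "CDK")),
            ("CDK*", Wildcard(None, "CDK")),
            ('note:"cell cycle arrest"', FieldTerm("note", "cell cycle arrest")),
            ("alpha.taxid:<=9606", Range("alpha.taxid", "<=", 9606.0)),
            ("(a OR b) AND c", And((Or((Term("a"), Term("b"))), Term("c")))),
        ],
    )
    def test_grammar(self, q, expected):
        assert parse_query(q) == expected

    def test_and_binds_tighter_than_or(self):
        ast = parse_query("a AND b OR c")
        assert ast == Or((And((Term("a"), Term("b"))), Term("c")))

    @pytest.mark.parametrize(
        "q",
        ["", "   ", "(a OR b", 'x:"unclosed', "a AND", "OR b", "a OR)", ":value"],
    )
    def test_errors_carry_position(self, q):
        with pytest.raises(QueryParseError) as excinfo:
            parse_query(q)
        assert excinfo.value.position >= 0


@pytest.fixture(scope="module")
def fix1_corpus():
    docs = [
        {"_id": "g1", "alpha": {"symbol": "CDK2", "taxid": 9606},
         "beta": {"pathway": ["cell_cycle", "dna_repair"], "notes": "unmapped later"}},
        {"_id": "g2", "alpha": {"symbol": "TP53", "taxid": 9606}},
    ]
    index, mapping = index_for(docs)
    return docs, index, mapping


class TestExecuteQuery:
    def test_bare_term_searches_all_keyword_paths(self, fix1_corpus):
        _docs, index, _mapping = fix1_corpus
        result = execute_query(index, parse_query("cdk2"))
        assert result.total == 1
        assert result.hits[0]["_id"] == "g1"

    def test_matching_is_case_insensitive_exact(self, fix1_corpus):
        _docs, index, _ = fix1_corpus
        assert execute_query(index, parse_query("CDK2")).total == 1
        assert execute_query(index, parse_query("CDK")).total == 0

    def test_range_with_tie_break_order(self, fix1_corpus):
        _docs, index, _ = fix1_corpus
        result = execute_query(index, parse_query("alpha.taxid:>9000"))
        assert result.total == 2
        assert [h["_id"] for h in result.hits] == ["g1", "g2"]

    def test_count_only_query(self, fix1_corpus):
        _docs, index, _ = fix1_corpus
        result = execute_query(index, parse_query("alpha.taxid:>9000"), from_=0, size=0)
        assert result.total == 2 and result.hits == []

    def test_list_values_index_each_element(self, fix1_corpus):
        _docs, index, _ = fix1_corpus
        assert execute_query(index, parse_query("beta.pathway:dna_repair")).total == 1

    def test_unmapped_path_raises_not_zero_hits(self, fix1_corpus):
        docs, index, mapping = fix1_corpus
        index.mapping.types.pop("beta.notes", None)
        with pytest.raises(UnqueryableFieldError, match="beta.notes"):
            execute_query(index, parse_query("beta.notes:unmapped"))

    def test_range_on_keyword_path_raises(self, fix1_corpus):
        _docs, index, _ = fix1_corpus
        with pytest.raises(UnqueryableFieldError):
            execute_query(index, parse_query("alpha.symbol:>5"))

    def test_size_cap_enforced(self, fix1_corpus):
        _docs, index, _ = fix1_corpus
        with pytest.raises(ValueError, match="cap"):
            execute_query(index, parse_query("cdk2"), size=2000)

    def test_empty_index_returns_zero(self):
        index, _ = index_for([])
        assert execute_query(index, Term("anything")).total == 0


class TestProjection:
    DOC = {"_id": "g1", "alpha": {"symbol": "CDK2", "taxid": 9606},
           "beta": {"pathway": ["cell_cycle"]}}

    def test_single_path(self):
        assert project_fields(self.DOC, ["alpha.symbol"]) == {
            "_id": "g1", "alpha": {"symbol": "CDK2"}
        }

    def test_missing_path_contributes_nothing(self):
        assert project_fields(self.DOC, ["nope"]) == {"_id": "g1"}

    def test_all_returns_full_document(self):
        assert project_fields(self.DOC, "all") == self.DOC

    def test_requested_path_includes_whole_subtree(self):
        assert project_fields(self.DOC, ["beta"]) == {
            "_id": "g1", "beta": {"pathway": ["cell_cycle"]}
        }


class TestGetById:
    def test_found_is_byte_exact(self, fix1_corpus):
        docs, index, _ = fix1_corpus
        assert get_by_id(index, "g1") == docs[0]

    def test_missing(self, fix1_corpus):
        _docs, index, _ = fix1_corpus
        assert get_by_id(index, "g9") is NOT_FOUND

    def test_ids_case_sensitive(self, fix1_corpus):
        _docs, index, _ = fix1_corpus
        assert get_by_id(index, "G1") is NOT_FOUND


class TestOracleEquivalence:
    """The module's central property: index results == linear-scan referee."""

    def test_random_asts_match_linear_scan(self):
        rng = random.Random(20240902)
        cases = 0
        for corpus_seed in range(12):
            corpus_rng = random.Random(1000 + corpus_seed)
            docs = synthetic_corpus(corpus_rng, corpus_rng.randint(20, 200))
            index, mapping = index_for(docs)
            vocabulary = corpus_vocabulary(docs, mapping)
            for _ in range(90):
                ast = random_ast(rng, mapping, vocabulary, depth=3)
                expected = oracle_query(docs, ast, mapping)
                result = execute_query(index, ast, from_=0, size=1000)
                got = {hit["_id"] for hit in result.hits}
                assert result.total == len(expected), ast
                assert got == expected, ast
                cases += 1
        assert cases >= 1000

    def test_pagination_pages_concatenate_losslessly(self):
        rng = random.Random(31)
        docs = synthetic_corpus(rng, 150)
        index, mapping = index_for(docs)
        vocabulary = corpus_vocabulary(docs, mapping)
        for _ in range(20):
            ast = random_ast(rng, mapping, vocabulary)
            full = [h["_id"] for h in execute_query(index, ast, 0, 1000).hits]
            for k in (1, 3, 7):
                pages = []
                offset = 0
                while True:
                    page = execute_query(index, ast, offset, k).hits
                    if not page:
                        break
                    pages.extend(h["_id"] for h in page)
                    offset += k
                assert pages == full, (ast, k)

    def test_determinism_across_runs(self):
        rng = random.Random(57)
        docs = synthetic_corpus(rng, 100)
        index1, mapping = index_for(docs)
        index2, _ = index_for(list(docs))
        vocabulary = corpus_vocabulary(docs, mapping)
        for _ in range(25):
            ast = random_ast(rng, mapping, vocabulary)
            a = execute_query(index1, ast, 0, 50)
            b = execute_query(index2, ast, 0, 50)
            assert a.hits == b.hits and a.total == b.total

    def test_mapped_iff_queryable(self):
        rng = random.Random(3)
        docs = synthetic_corpus(rng, 40)
        index, mapping = index_for(docs)
        from annohub.documents import iter_paths

        report_paths = {p for doc in docs for p, _v, _l in iter_paths(doc)}
        for path in sorted(report_paths):
            queryable = path in mapping.queryable_paths()
            try:
                execute_query(index, FieldTerm(path=path, value="1"))
                assert queryable, path
            except UnqueryableFieldError:
                assert not queryable, path
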