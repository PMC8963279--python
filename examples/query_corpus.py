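"""Parse and execute queries against an embedded inverted index.

Builds a 100-document synthetic corpus, auto-generates its mapping, and
runs a few representative query strings: a bare term (searched across all
keyword paths), a numeric range, a boolean combination, and a prefix
wildcard.  Totals are exact match counts; hits come back ranked by
per-document match count with ascending-id tie-breaks.
"""

import random

from annohub import build_index, execute_query, generate_mapping, inspect_documents, parse_query
from annohub.fixtures import synthetic_corpus
from annohub.merge import BuildResult

docs = synthetic_corpus(random.Random(42), 100)
mapping = generate_mapping(inspect_documents(docs))
index = build_index(BuildResult(merged=docs, metadata=None), mapping)
print(f"indexed {index.total_documents} documents, "
      f"{len(mapping.queryable_paths())} queryable paths")

for q in (
    "cdk2",
    "anno.taxid:9606",
    "anno.score:>=5 AND path.pathway:apoptosis",
    "anno.symbol:BR*",
    "tp53 OR myc",
):
    result = execute_query(index, parse_query(q), from_=0, size=3)
    ids = [hit["_id"] for hit in result.hits]
    print(f"q={q!r}: total={result.total}, first hits={ids}")
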