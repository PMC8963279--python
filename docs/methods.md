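# Methods

This note documents the models, contracts and numerical choices behind
`annohub`, and what the synthetic test corpora do and do not demonstrate.

## The document model

The unit of every stage is the *annotation document*: a JSON-style tree
with a unique string `_id` (≤ 512 bytes, no surrounding whitespace, compared
byte-wise and case-sensitively). Leaves are strings, integers, finite
floats or booleans; inner nodes are objects or lists. Keys may not contain
`.` (reserved for dotted path notation) or start with `$` (document-store
operator prefix), so documents remain portable to common external backends.
Validation reports *all* violations of a document at once and performs no
coercion — an integer-valued float stays a float, and numeric strings stay
strings throughout the system.

## Release identity and the dump stage

A source release is identified by content: the SHA-256 of the payload (for
directory sources, a digest over the sorted `(relative path, file digest)`
pairs). Modification times and HTTP validators (`Last-Modified`/`ETag`)
only label the release folder; for `file://` sources the label is the UTC
mtime formatted to seconds plus an 8-hex-character checksum prefix, which
keeps lexicographic folder order aligned with time while disambiguating
content changes within one second. Consequences: touching a file without
changing bytes is *not* a new release, and detection is a pure function of
source content — two consecutive checks with no change always agree.
Dumps write to a temp folder and rename into place only after re-verifying
checksums, so an interrupted or corrupted dump leaves the release list
exactly as it was. Supported schemes are `file://` and `http(s)://`;
retrieval uses the standard library's `urllib`.

## Cron schedules

Refresh schedules use the classic five-field cron dialect (minute, hour,
day-of-month, month, day-of-week; `*`, lists, ranges, `/step`; dow 0–7 with
0 and 7 = Sunday; when both day fields are restricted, either may match).
Evaluation is pure — `schedule_due(descriptor, last_run, now)` is true iff
a firing lies in `(last_run, now]` — and the implementation walks candidate
days rather than minutes, so cost scales with the window length in days.
The tests referee it against brute-force minute enumeration. Scheduling is
advisory: `annohub status` reports due sources, but no daemon runs inside
the package; an external scheduler is expected to invoke `annohub dump`.

## Upload semantics

A plugin's parser is a callable receiving the dump folder path and lazily
yielding raw trees (the engine consumes it as a stream). Within one
release stream, duplicate `_id`s resolve last-write-wins and are counted;
invalid documents are skipped with per-ordinal reasons; `accepted +
rejected` always equals the number of documents emitted. The
`(source, release)` namespace is replaced wholesale on success — re-upload
is byte-idempotent — and a parser exception aborts the whole upload with
the namespace untouched. To provide the dedup, sorted persistence and
all-or-nothing guarantees, one release's accepted documents are buffered in
memory before the atomic replace; this bounds practical corpus size per
source to available memory, which matches the package's scale (reference
stores are in-memory and sorted JSON-lines on disk).

## Merge policy

Merging is *source-namespaced*: a merged document places each contributing
source's body under a top-level key equal to the source name (emitted in
sorted-name order for byte determinism). This makes the merge total,
lossless and invariant to source order — there is no field-level conflict
to resolve, which is why the per-source `priority` is carried but unused by
the merge itself. Root sources implement identifier gating: when the root
set is non-empty, an id must occur in at least one root source to enter the
build, so `merged + root_excluded = |union of ids|`. Identifier matching
is exact byte equality; reconciling aliases across identifier systems is
deliberately out of scope. Build versions are
`<config name>.<UTC yyyymmddHHMMSS>` with a `-N` suffix on same-second
collisions.

## Type inspection and the mapping

The inspector streams documents once, profiling each dotted path's observed
types (memory linear in distinct paths, not corpus size). Lists are
transparent — they flag the profile but do not extend the path — mirroring
search-engine array semantics, so a scalar in one document and a list of
scalars in another is *not* a conflict. An empty list carries no type
evidence and therefore no observation. The mapping derives from a join on
the type lattice:

| observed set | mapped type |
|---|---|
| `{integer}` | `integer` |
| `{integer, float}` / `{float}` | `float` |
| any set containing `string` (no subtree) | `keyword` |
| `{boolean}` | `boolean`; boolean mixed with anything → `keyword` |
| `{subtree}` | `object` |
| subtree + scalar | **conflict** — excluded |

The join is classification of the set union, hence commutative,
associative and idempotent by construction. A conflict path is listed
excluded with reason `object/scalar conflict`; paths beneath it are neither
mapped nor separately listed — they are covered by the excluded ancestor,
and the soundness property is stated accordingly (every observed path is
mapped, excluded, or under an excluded ancestor). Strings map to
exact-match `keyword` (lowercase-normalized at index and query time), not
analyzed text, which keeps matching bit-exactly checkable.

## Query engine

The grammar is a deliberate minimal contract: fielded terms (`path:value`),
numeric ranges (`path:>n`, `>=`, `<`, `<=`), prefix wildcards (trailing
`*`), bare terms searched over every keyword path, uppercase `AND`/`OR`
with `AND` binding tighter, parentheses, double quotes preserving spaces,
and adjacency as implicit `AND`. Parse errors carry a character position.

Execution is set-algebraic (intersection/union) over the inverted index.
On keyword paths every scalar is indexed under its canonical lowercase
string form (booleans as `true`/`false`), so mixed-type fields the
inspector joins to `keyword` stay uniformly queryable; on numeric and
boolean paths, contrary-typed values are skipped from the index and counted
(`skipped_values`), while the document itself remains stored and
retrievable in full. Fielded queries on unmapped or mistyped paths raise
an explicit error rather than returning zero hits, making the
indexed-versus-stored distinction observable.

Ranking is fully deterministic: documents order by descending total leaf
match count (a bare term contributes one count per keyword path it matches)
with ties broken by ascending `_id`; `total` is independent of pagination
and `size=0` gives a count-only result. The engine's matching sets are
refereed against `fixtures.oracle_query`, an index-free per-document
recursive scan, over randomized corpora and query trees. Defaults follow
the common annotation-API conventions: `size=10`, `from=0`, cap
`size ≤ 1000`.

## Service layer

The REST layer is handlers returning `(status, body)` pairs wrapped by a
thin stdlib WSGI app — the HTTP response is by construction the same object
the library call returns, which the tests assert directly. Error responses
share one envelope `{"success": false, "error": ..., "code": ...}`. Batch
resolution (`POST /query`, ≤ 1000 ids) preserves request order, marks
misses `{"query": id, "notfound": true}`, and with non-`_id` scopes may
yield multiple adjacent elements per requested id. `took` is wall-clock
milliseconds and excluded from all equality checks. One service instance
serves exactly one build version.

## Synthetic data

The generator (`annohub.fixtures`) emulates the *structural* properties the
pipeline must handle — controlled identifier overlap between sources,
TSV/CSV/JSON-lines payloads with complete plugins (dogfooding the
registry), nesting to depth 3, list-valued fields, int/float mixtures, and
injected object/scalar conflicts — with truth tables (id sets, expected
merged ids under any root choice, path→type profiles, conflict paths)
recorded during generation, never re-derived. It does not emulate real
annotation content, identifier-system aliasing, multi-gigabyte corpora or
malformed encodings; passing tests therefore demonstrate the integration,
typing and query contracts, not robustness to arbitrary real-world feeds.
Generation is deterministic: each source draws from its own
counter-derived `random.Random` stream, so the same `(seed, spec)` yields
byte-identical payloads and adding a source never perturbs the others.

## Problem sizes and tolerances

The verification suites use corpora of 20–200 documents, 200 randomized
merge layouts, exhaustive lattice checks over all 31 non-empty type sets,
and 1000+ random query trees of depth ≤ 3 — sizes at which the brute-force
referees (set algebra, recursive enumeration, linear scan) are themselves
trivially auditable. All checks are exact (set equality, byte equality);
no numerical tolerances are involved anywhere in the package.

## Known limitations

Uploads buffer one release in memory; the embedded index rebuilds its
inverted structures from `merged.jsonl` on load (the on-disk index format
stores only the mapping and counts, documented as non-portable); `ftp`,
`git` and cloud-drive retrieval, resumable downloads and authentication are
out of scope; there is no relevance scoring, fuzzy matching or
aggregations; and the optional external MongoDB/Elasticsearch adapters the
store and index contracts are shaped for are not included.
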