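# annohub

A plugin-driven data hub and query service for biomedical annotations.

Many groups need the same piece of infrastructure: take several annotation
sources for one entity type (genes, variants, chemicals, …) — each with its
own file format, update cadence and field vocabulary — and turn them into a
single, queryable, always-up-to-date service keyed by entity identifier.
`annohub` implements that pipeline end to end, fully offline-testable:

```
register ──► dump ──► upload ──► build ──► inspect ──► index ──► serve
(plugin)   (fetch,   (parse +   (merge by  (profile    (inverted  (REST:
            version) validate)  shared id) types, map) index)     /gene/{id},
                                                                  /query, …)
```

* **Plugin** — a directory with a `manifest.json` (source name, `file://` or
  `http(s)://` location, parser entry point, optional five-field cron
  schedule, merge priority) and a `parser.py` that lazily yields JSON-style
  documents, each carrying a unique string `_id`.
* **Dump** — payloads are fetched into content-addressed release folders;
  a release is defined by its SHA-256 checksum, so unchanged sources are
  skipped and every dump is atomic.
* **Upload** — parsed documents are validated (key hygiene, finite leaves,
  `_id` constraints) and stored per `(source, release)` with last-write-wins
  duplicate handling; a mid-stream parser fault leaves the store untouched.
* **Build** — documents sharing an `_id` across sources merge into one
  document per entity, each source's body under its own top-level key, so
  the merge is lossless and independent of source order. *Root sources*
  gate membership: an id absent from every root source is excluded.
* **Inspect** — every field path's observed types are profiled and joined
  on a type lattice (`{integer, float} → float`, anything with a string →
  `keyword`, subtree+scalar → conflict) to propose an Elasticsearch-style
  mapping. Numeric strings are never promoted.
* **Index / serve** — only mapped paths are queryable; unmapped fields are
  still stored and served byte-exact by id, but fielded queries on them
  raise an explicit "unqueryable field" error. The embedded index supports
  exact keyword terms (lowercase-normalized), numeric ranges, prefix
  wildcards and `AND`/`OR` composition with deterministic ranking.

## Worked example

```python
import json, tempfile
from pathlib import Path
from annohub import BuildConfig, Hub
from annohub.fixtures import generate_fix1

workdir = Path(tempfile.mkdtemp())
truth = generate_fix1(workdir / "fix1")     # two tiny gene sources
hub = Hub(workdir / "data")
for name in ("alpha", "beta"):
    hub.register(truth.plugin_dirs[name])
    hub.dump(name)
    hub.upload(name)
build = hub.build(BuildConfig(
    name="demo",
    sources=[("alpha", "latest"), ("beta", "latest")],
    root_sources=["alpha"],
))
print(build.metadata.merged_count, build.metadata.root_excluded_count)
print(json.dumps(build.merged[0]))
```

prints

```
2 1
{"_id": "g1", "alpha": {"symbol": "CDK2", "taxid": 9606}, "beta": {"pathway": ["cell_cycle", "dna_repair"]}}
```

`alpha` holds genes g1 and g2, `beta` holds g1 and g3. With `alpha` as the
root source the merged corpus contains exactly the 2 ids present in alpha
(g3 is the 1 root-excluded id), and g1 carries both sources' annotations,
each under its own namespace. `hub.index(...)` and `hub.serve(...)` then
expose `GET /gene/g1`, `GET /query?q=cdk2`, batch `POST /query` and
`/metadata` over HTTP. The `examples/` directory contains one short script
per capability (pipeline, inspection, querying, serving), and the same
workflow is available from the shell via the `annohub` console command
(`register`, `dump`, `upload`, `build`, `inspect`, `index`, `serve`,
`status`).

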