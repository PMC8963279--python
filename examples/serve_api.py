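"""Serve a merged, indexed build over HTTP and call its endpoints.

Demonstrates the four endpoint families: annotation by id (with field
projection), query, batch (with notfound markers), and metadata.  The
batch response preserves request order and marks misses explicitly.
"""

import json
import tempfile
import urllib.error
import urllib.request
from pathlib import Path

from annohub import BuildConfig, Hub
from annohub.fixtures import generate_fix1

workdir = Path(tempfile.mkdtemp())
truth = generate_fix1(workdir / "fix1")
hub = Hub(workdir / "data")
for name in ("alpha", "beta"):
    hub.register(truth.plugin_dirs[name])
    hub.dump(name)
    hub.upload(name)
build = hub.build(BuildConfig(
    name="demo", sources=[("alpha", "latest"), ("beta", "latest")]
))
hub.index(build.metadata.build_version)
server = hub.serve(build.metadata.build_version, entity="gene")
server.start_background()
base = f"http://127.0.0.1:{server.port}"


def get(path):
    try:
        with urllib.request.urlopen(base + path) as response:
            return json.loads(response.read())
    except urllib.error.HTTPError as exc:
        return json.loads(exc.read())


print("GET /gene/g1?fields=alpha.symbol ->", get("/gene/g1?fields=alpha.symbol"))
print("GET /query?q=cdk2 -> total", get("/query?q=cdk2")["total"])
request = urllib.request.Request(
    base + "/query",
    data=json.dumps({"ids": ["g1", "g9"]}).encode(),
    headers={"Content-Type": "application/json"},
)
with urllib.request.urlopen(request) as response:
    print("POST /query ids=[g1,g9] ->", json.loads(response.read()))
print("GET /metadata/fields ->", get("/metadata/fields"))
server.shutdown()
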