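"""Shared pipeline fixtures built on the synthetic-source generator."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from annohub import BuildConfig, Hub
from annohub.fixtures import FixtureTruth, generate_fix1
from annohub.index import Index, build_index
from annohub.inspection import IndexMapping, generate_mapping, inspect_documents
from annohub.merge import BuildResult


@dataclass
class Pipeline:
    hub: Hub
    truth: FixtureTruth
    build: BuildResult
    mapping: IndexMapping
    index: Index


def run_fix1_pipeline(root, roots=("alpha",)) -> Pipeline:
    """register -> dump -> upload -> build -> inspect -> index over FIX1."""
    truth = generate_fix1(root / "fix1")
    hub = Hub(root / "data")
    for name, plugin_dir in truth.plugin_dirs.items():
        hub.register(plugin_dir)
        hub.dump(name)
        hub.upload(name)
    cfg = BuildConfig(
        name="fix1",
        sources=[("alpha", "latest"), ("beta", "latest")],
        root_sources=list(roots),
    )
    build = hub.build(cfg)
    report, mapping = hub.inspect(build.metadata.build_version)
    index = hub.index(build.metadata.build_version, mapping)
    return Pipeline(hub=hub, truth=truth, build=build, mapping=mapping, index=index)


@pytest.fixture(scope="session")
def fix1(tmp_path_factory) -> Pipeline:
    return run_fix1_pipeline(tmp_path_factory.mktemp("fix1"))


@pytest.fixture()
def fix1_fresh(tmp_path) -> Pipeline:
    return run_fix1_pipeline(tmp_path)


def index_for(docs: list[dict]) -> tuple[Index, IndexMapping]:
    """Inspect an in-memory corpus and build its index + generated mapping."""
    mapping = generate_mapping(inspect_documents(docs))
    build = BuildResult(merged=sorted(docs, key=lambda d: d["_id"]), metadata=None)
    return build_index(build, mapping), mapping
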