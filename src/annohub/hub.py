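"""The hub facade: one object tying registry, dump, upload, build, inspect,
index and serve together over a single data root.

Everything the CLI does goes through this class, so any console workflow is
reproducible from Python alone.  Layout under the data root::

    registry.json                    # descriptors + per-source state
    <source>/<release>/...           # dumped payloads + release.json
    store/<source>/<release>.jsonl   # uploaded documents
    builds/<version>/                # merged.jsonl + build.json + index/
"""

from __future__ import annotations

from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from .dump import SKIPPED, DumpResult, dump_source, list_local_releases, release_folder
from .errors import AnnoHubError
from .inspection import IndexMapping, InspectionReport, generate_mapping, inspect_documents
from .index import Index, build_index, save_index, load_index
from .merge import BuildConfig, BuildResult, list_builds, load_build, run_build
from .registry import Registry, SourceDescriptor, load_manifest, schedule_due
from .service import AnnotationService, ServiceConfig, ServiceServer
from .store import JsonLinesStore
from .upload import UploadStats, upload_source


class Hub:
    def __init__(self, data_root: str | Path):
        self.data_root = Path(data_root)
        self.data_root.mkdir(parents=True, exist_ok=True)
        self.registry_path = self.data_root / "registry.json"
        self.registry = Registry.load(self.registry_path)
        self.store = JsonLinesStore(self.data_root)

    def _save(self) -> None:
        self.registry.save(self.registry_path)

    def _descriptor(self, source: str) -> SourceDescriptor:
        descriptor = self.registry.get(source)
        if descriptor is None:
            raise AnnoHubError(f"source {source!r} is not registered")
        return descriptor

    # -- stages ----------------------------------------------------------

    def register(self, plugin_dir: str | Path) -> SourceDescriptor:
        descriptor = load_manifest(plugin_dir)
        self.registry.register(descriptor)
        self._save()
        return descriptor

    def dump(self, source: str, force: bool = False):
        descriptor = self._descriptor(source)
        result = dump_source(descriptor, self.data_root, force=force)
        if isinstance(result, DumpResult):
            state = self.registry.get_state(source)
            state["last_release"] = result.release.value
            state["last_dump_time"] = datetime.now(timezone.utc).isoformat()
            self._save()
        return result

    def upload(self, source: str, release: Optional[str] = None) -> UploadStats:
        descriptor = self._descriptor(source)
        if release is None:
            releases = list_local_releases(source, self.data_root)
            if not releases:
                raise AnnoHubError(f"source {source!r} has never been dumped")
            release = releases[-1].value
        folder = release_folder(source, release, self.data_root)
        stats = upload_source(descriptor, release, self.store, folder)
        state = self.registry.get_state(source)
        state["last_upload_time"] = datetime.now(timezone.utc).isoformat()
        state["last_upload_release"] = release
        state["doc_count"] = stats.accepted - stats.duplicate_ids_collapsed
        self._save()
        return stats

    def build(self, cfg: BuildConfig | str | Path) -> BuildResult:
        if not isinstance(cfg, BuildConfig):
            cfg = BuildConfig.load(cfg)
        return run_build(cfg, self.store, data_root=self.data_root)

    def inspect(self, build_version: str) -> tuple[InspectionReport, IndexMapping]:
        build = load_build(self.data_root, build_version)
        report = inspect_documents(build.merged)
        return report, generate_mapping(report)

    def index(
        self, build_version: str, mapping: Optional[IndexMapping | str | Path] = None
    ) -> Index:
        build = load_build(self.data_root, build_version)
        if mapping is None:
            mapping = generate_mapping(inspect_documents(build.merged))
        elif not isinstance(mapping, IndexMapping):
            mapping = IndexMapping.load(mapping)
        idx = build_index(build, mapping)
        assert build.folder is not None
        save_index(idx, build.folder)
        return idx

    def serve(
        self,
        build_version: str,
        entity: str = "gene",
        port: int = 0,
        host: str = "127.0.0.1",
    ) -> ServiceServer:
        idx, build = load_index(self.data_root, build_version)
        service = AnnotationService(
            idx, metadata=build.metadata, config=ServiceConfig(entity=entity, port=port)
        )
        return ServiceServer(service, host=host, port=port)

    # -- status ----------------------------------------------------------

    def status(self, now: Optional[datetime] = None) -> dict:
        now = now or datetime.now(timezone.utc).replace(tzinfo=None)
        sources = {}
        for name in self.registry.names():
            descriptor = self.registry.get(name)
            assert descriptor is not None
            state = self.registry.state.get(name, {})
            last_dump = state.get("last_dump_time")
            last_dt = (
                datetime.fromisoformat(last_dump).replace(tzinfo=None)
                if last_dump
                else None
            )
            sources[name] = {
                "location": descriptor.location,
                "schedule": descriptor.schedule,
                "priority": descriptor.priority,
                "last_release": state.get("last_release"),
                "last_dump_time": last_dump,
                "last_upload_time": state.get("last_upload_time"),
                "doc_count": state.get("doc_count"),
                "due": schedule_due(descriptor, last_dt, now),
            }
        builds = {}
        for version in list_builds(self.data_root):
            build = load_build(self.data_root, version)
            assert build.folder is not None
            builds[version] = {
                "documents": build.metadata.merged_count,
                "indexed": (build.folder / "index" / "mapping.json").is_file(),
            }
        return {"data_root": str(self.data_root), "sources": sources, "builds": builds}
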