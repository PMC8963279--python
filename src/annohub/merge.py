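"""Build stage: merge per-source documents sharing an identifier into one
document per entity.

The merge policy is source-namespaced: each contributing source's body is
placed under a top-level key equal to the source name, which makes the merge
total, order-invariant and lossless — no field-level conflict resolution is
needed.  Root sources gate membership: when the root set is non-empty, an
identifier must occur in at least one root source to enter the build.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from .errors import BuildError
from .store import DocumentStore

LATEST = "latest"


@dataclass
class BuildConfig:
    """Which sources (and which are roots) merge into one corpus."""

    name: str
    sources: list[tuple[str, str]]  # (source name, "latest" or explicit release tag)
    root_sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s for s, _sel in self.sources]
        if not names:
            raise BuildError("build config must list at least one source")
        if len(set(names)) != len(names):
            raise BuildError("build config source names must be distinct")
        unknown_roots = set(self.root_sources) - set(names)
        if unknown_roots:
            raise BuildError(
                f"root sources not among configured sources: {sorted(unknown_roots)}"
            )

    @classmethod
    def from_json(cls, data: dict) -> "BuildConfig":
        sources = []
        for item in data.get("sources", []):
            if isinstance(item, str):
                sources.append((item, LATEST))
            else:
                sources.append((item["name"], item.get("release", LATEST)))
        return cls(
            name=data["name"],
            sources=sources,
            root_sources=list(data.get("root_sources", [])),
        )

    @classmethod
    def load(cls, path: str | Path) -> "BuildConfig":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class BuildPlan:
    config: BuildConfig
    resolved: list[tuple[str, str]]  # (source, concrete release tag)
    ids_per_source: dict[str, set[str]]
    union_ids: set[str]
    root_ids: set[str]  # union over root sources; equals union_ids when no roots

    @property
    def merged_ids(self) -> set[str]:
        return self.union_ids & self.root_ids


@dataclass
class BuildMetadata:
    build_name: str
    build_version: str
    sources: dict[str, dict]  # source -> {"release", "documents"}
    merged_count: int
    root_excluded_count: int

    def to_json(self) -> dict:
        return {
            "build_name": self.build_name,
            "build_version": self.build_version,
            "sources": self.sources,
            "merged_count": self.merged_count,
            "root_excluded_count": self.root_excluded_count,
        }


@dataclass
class BuildResult:
    merged: list[dict]  # ascending _id
    metadata: BuildMetadata
    folder: Optional[Path] = None


def plan_build(cfg: BuildConfig, store: DocumentStore) -> BuildPlan:
    """Resolve release selectors and census identifiers per source.

    ``latest`` resolves to the highest release tag; a source with no uploaded
    release matching its selector is a build error naming the source.
    """
    resolved: list[tuple[str, str]] = []
    ids_per_source: dict[str, set[str]] = {}
    for source, selector in cfg.sources:
        releases = store.releases(source)
        if not releases:
            raise BuildError(f"source {source!r} has no uploaded release")
        release = releases[-1] if selector == LATEST else selector
        if release not in releases:
            raise BuildError(
                f"source {source!r} has no uploaded release {release!r}"
            )
        resolved.append((source, release))
        ids_per_source[source] = store.ids(source, release)
    union_ids = set().union(*ids_per_source.values())
    if cfg.root_sources:
        root_ids = set().union(*(ids_per_source[s] for s in cfg.root_sources))
    else:
        root_ids = set(union_ids)
    return BuildPlan(
        config=cfg,
        resolved=resolved,
        ids_per_source=ids_per_source,
        union_ids=union_ids,
        root_ids=root_ids,
    )


def merge_documents(
    per_source: list[tuple[str, int, dict]], cfg: Optional[BuildConfig] = None
) -> dict:
    """Merge same-id documents from several sources into one namespaced tree.

    Each source's body lands under a top-level key equal to the source name
    (sources are emitted in sorted-name order so the result is independent of
    input order); a source contributing an empty body contributes nothing.
    """
    if not per_source:
        raise BuildError("merge_documents requires at least one input")
    ids = {doc["_id"] for _src, _prio, doc in per_source}
    if len(ids) != 1:
        raise BuildError(f"merge inputs must share one _id, got {sorted(ids)}")
    merged: dict = {"_id": ids.pop()}
    for source, _priority, doc in sorted(per_source, key=lambda t: t[0]):
        body = {k: v for k, v in doc.items() if k != "_id"}
        if body:
            merged[source] = body
    return merged


def _new_build_version(name: str, builds_dir: Path, now: datetime) -> str:
    base = f"{name}.{now.strftime('%Y%m%d%H%M%S')}"
    version = base
    suffix = 0
    while (builds_dir / version).exists():
        suffix += 1
        version = f"{base}-{suffix}"
    return version


def run_build(
    cfg: BuildConfig,
    store: DocumentStore,
    data_root: Optional[str | Path] = None,
    now: Optional[datetime] = None,
) -> BuildResult:
    """Merge the configured sources into one corpus and persist it.

    Emits one merged document per identifier in the union of source ids,
    gated by the root-source rule, in ascending ``_id``.  When ``data_root``
    is given, the corpus is persisted under ``builds/<build_version>/`` as a
    sorted ``merged.jsonl`` plus a ``build.json`` metadata file; a failure
    leaves no partial build directory.
    """
    plan = plan_build(cfg, store)
    docs_by_source = {
        source: {d["_id"]: d for d in store.iter_docs(source, release)}
        for source, release in plan.resolved
    }
    priorities = {source: idx + 1 for idx, (source, _rel) in enumerate(cfg.sources)}
    merged: list[dict] = []
    for _id in sorted(plan.merged_ids):
        contributions = [
            (source, priorities[source], docs_by_source[source][_id])
            for source, _release in plan.resolved
            if _id in docs_by_source[source]
        ]
        merged.append(merge_documents(contributions, cfg))

    now = now or datetime.now(timezone.utc)
    builds_dir = Path(data_root) / "builds" if data_root else None
    version = _new_build_version(
        cfg.name, builds_dir if builds_dir else Path("."), now
    ) if builds_dir else f"{cfg.name}.{now.strftime('%Y%m%d%H%M%S')}"
    metadata = BuildMetadata(
        build_name=cfg.name,
        build_version=version,
        sources={
            source: {"release": release, "documents": len(docs_by_source[source])}
            for source, release in plan.resolved
        },
        merged_count=len(merged),
        root_excluded_count=len(plan.union_ids) - len(plan.merged_ids),
    )
    result = BuildResult(merged=merged, metadata=metadata)
    if builds_dir is not None:
        builds_dir.mkdir(parents=True, exist_ok=True)
        temp = builds_dir / f".tmp-{version}"
        if temp.exists():
            shutil.rmtree(temp)
        temp.mkdir()
        try:
            with open(temp / "merged.jsonl", "w", encoding="utf-8") as handle:
                for doc in merged:
                    handle.write(json.dumps(doc, ensure_ascii=False, sort_keys=True))
                    handle.write("\n")
            (temp / "build.json").write_text(
                json.dumps(metadata.to_json(), indent=2), encoding="utf-8"
            )
        except Exception:
            shutil.rmtree(temp, ignore_errors=True)
            raise
        final = builds_dir / version
        temp.rename(final)
        result.folder = final
    return result


def load_build(data_root: str | Path, build_version: str) -> BuildResult:
    """Load a persisted build back into memory."""
    folder = Path(data_root) / "builds" / build_version
    if not folder.is_dir():
        raise BuildError(f"no such build: {build_version!r}")
    meta = json.loads((folder / "build.json").read_text(encoding="utf-8"))
    merged = []
    with open(folder / "merged.jsonl", encoding="utf-8") as handle:
        for line in handle:
            if line.strip():
                merged.append(json.loads(line))
    metadata = BuildMetadata(
        build_name=meta["build_name"],
        build_version=meta["build_version"],
        sources=meta["sources"],
        merged_count=meta["merged_count"],
        root_excluded_count=meta["root_excluded_count"],
    )
    return BuildResult(merged=merged, metadata=metadata, folder=folder)


def list_builds(data_root: str | Path) -> list[str]:
    builds_dir = Path(data_root) / "builds"
    if not builds_dir.is_dir():
        return []
    return sorted(
        p.name for p in builds_dir.iterdir()
        if p.is_dir() and (p / "build.json").is_file()
    )
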