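"""Upload stage: run a plugin's parser over a dumped release and load the
validated documents into a per-source store.

The namespace ``(source, release)`` is replaced wholesale on success, so
re-uploading the same release is idempotent.  A parser exception aborts the
whole upload and leaves the namespace exactly as it was (all-or-nothing).
Invalid documents are skipped and counted; duplicate ``_id`` within one
stream resolves last-write-wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .documents import validate_document
from .dump import ReleaseTag
from .errors import UploadError
from .registry import SourceDescriptor, resolve_parser
from .store import DocumentStore


@dataclass
class UploadStats:
    source: str
    release: str
    accepted: int = 0
    rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)
    duplicate_ids_collapsed: int = 0

    @property
    def emitted(self) -> int:
        return self.accepted + self.rejected


def run_parser(descriptor: SourceDescriptor, dump_folder: str | Path) -> Iterator[dict]:
    """Invoke the plugin's parser callable on the dump folder.

    The callable must yield raw document trees lazily; this wrapper simply
    resolves the entry point and hands over the folder path.
    """
    dump_folder = Path(dump_folder)
    if not dump_folder.is_dir():
        raise UploadError(f"dump folder does not exist: {dump_folder}")
    parser = resolve_parser(descriptor)
    return iter(parser(str(dump_folder)))


def upload_source(
    descriptor: SourceDescriptor,
    release: ReleaseTag | str,
    store: DocumentStore,
    dump_folder: str | Path,
) -> UploadStats:
    """Parse, validate and store every document of one dumped release.

    Raises :class:`UploadError` (namespace untouched) when the parser raises
    mid-stream; the error records the ordinal of the last good document.
    """
    release_value = release.value if isinstance(release, ReleaseTag) else release
    stats = UploadStats(source=descriptor.name, release=release_value)
    buffered: dict[str, dict] = {}
    stream = run_parser(descriptor, dump_folder)
    ordinal = 0
    while True:
        try:
            raw = next(stream)
        except StopIteration:
            break
        except Exception as exc:
            raise UploadError(
                f"parser for source {descriptor.name!r} failed after "
                f"{ordinal} document(s): {exc}",
                last_good_ordinal=ordinal,
            ) from exc
        ordinal += 1
        violations = validate_document(raw)
        if violations:
            stats.rejected += 1
            stats.rejections.append((ordinal, "; ".join(violations)))
            continue
        stats.accepted += 1
        if raw["_id"] in buffered:
            stats.duplicate_ids_collapsed += 1
        buffered[raw["_id"]] = raw
    store.replace(descriptor.name, release_value, buffered)
    return stats
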