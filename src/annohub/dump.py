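"""Dump stage: retrieve source payloads into versioned local release folders.

Release identity is content-based: a SHA-256 checksum is always computed,
with file modification times / HTTP validators serving as sortable labels.
Dumps are atomic — payloads land in a temp folder that is renamed into place
only after checksum verification, so a failed dump leaves no trace.

On-disk layout::

    <data_root>/<source>/<release>/...payload...
    <data_root>/<source>/<release>/release.json   # tag, origin, time, file checksums
"""

from __future__ import annotations

import hashlib
import json
import shutil
import urllib.error
import urllib.request
from dataclasses import dataclass
from datetime import datetime, timezone
from email.utils import parsedate_to_datetime
from pathlib import Path
from typing import Optional, Union
from urllib.parse import urlparse, unquote

from .errors import DumpError, RetrievalError
from .registry import SourceDescriptor

SIDECAR_NAME = "release.json"


class _Unchanged:
    def __repr__(self) -> str:  # pragma: no cover
        return "UNCHANGED"


class _Skipped:
    def __repr__(self) -> str:  # pragma: no cover
        return "SKIPPED"


#: Sentinel returned by detect_release when the source equals the known tag.
UNCHANGED = _Unchanged()
#: Sentinel returned by dump_source when nothing new was retrieved.
SKIPPED = _Skipped()


@dataclass(frozen=True)
class ReleaseTag:
    """A sortable release label plus the content checksum that defines identity."""

    value: str
    origin: str  # mtime | http-header | checksum | manual
    checksum: str

    def __eq__(self, other: object) -> bool:
        # Release identity = content; labels are hints.
        if isinstance(other, ReleaseTag):
            return self.checksum == other.checksum
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.checksum)


@dataclass
class DumpResult:
    source: str
    release: ReleaseTag
    files: list[tuple[str, int, str]]  # (relative path, byte size, sha256)
    folder: Path


def _sha256_file(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _file_url_path(location: str) -> Path:
    parsed = urlparse(location)
    return Path(unquote(parsed.path))


def _mtime_label(timestamp: float) -> str:
    return datetime.fromtimestamp(timestamp, tz=timezone.utc).strftime(
        "%Y-%m-%dT%H-%M-%S"
    )


def _local_fingerprint(path: Path) -> tuple[str, float, list[tuple[str, int, str]]]:
    """Checksum + newest mtime + per-file manifest for a file or directory."""
    if path.is_file():
        sha = _sha256_file(path)
        return sha, path.stat().st_mtime, [(path.name, path.stat().st_size, sha)]
    if path.is_dir():
        entries = sorted(
            p for p in path.rglob("*") if p.is_file() and p.name != SIDECAR_NAME
        )
        if not entries:
            raise RetrievalError(f"source directory is empty: {path}")
        digest = hashlib.sha256()
        files = []
        newest = 0.0
        for entry in entries:
            rel = entry.relative_to(path).as_posix()
            sha = _sha256_file(entry)
            digest.update(rel.encode())
            digest.update(sha.encode())
            files.append((rel, entry.stat().st_size, sha))
            newest = max(newest, entry.stat().st_mtime)
        return digest.hexdigest(), newest, files
    raise RetrievalError(f"unreachable location: {path} does not exist")


def _http_fetch(location: str) -> tuple[bytes, Optional[str]]:
    """Fetch an http(s) payload; returns (body, Last-Modified header or None)."""
    try:
        with urllib.request.urlopen(location, timeout=30) as response:
            body = response.read()
            last_modified = response.headers.get("Last-Modified")
            etag = response.headers.get("ETag")
    except (urllib.error.URLError, OSError) as exc:
        raise RetrievalError(f"unreachable location {location!r}: {exc}") from exc
    return body, last_modified or etag


def detect_release(
    descriptor: SourceDescriptor, known: Optional[ReleaseTag] = None
) -> Union[ReleaseTag, _Unchanged]:
    """Compute the source's current release tag, or UNCHANGED if it equals ``known``.

    file:// tags combine the newest modification time with a content checksum
    prefix (lexicographic order of labels tracks time); http(s):// tags derive
    from the Last-Modified/ETag validator, falling back to the checksum alone.
    Equality with ``known`` is checksum-only.
    """
    scheme = urlparse(descriptor.location).scheme
    if scheme == "file":
        path = _file_url_path(descriptor.location)
        checksum, mtime, _files = _local_fingerprint(path)
        tag = ReleaseTag(
            value=f"{_mtime_label(mtime)}-{checksum[:8]}",
            origin="mtime",
            checksum=checksum,
        )
    elif scheme in ("http", "https"):
        body, validator = _http_fetch(descriptor.location)
        checksum = hashlib.sha256(body).hexdigest()
        if validator:
            try:
                stamp = _mtime_label(parsedate_to_datetime(validator).timestamp())
                value = f"{stamp}-{checksum[:8]}"
            except (TypeError, ValueError):
                value = f"etag-{checksum[:16]}"
            tag = ReleaseTag(value=value, origin="http-header", checksum=checksum)
        else:
            tag = ReleaseTag(
                value=f"sha-{checksum[:16]}", origin="checksum", checksum=checksum
            )
    else:
        raise RetrievalError(f"unsupported location scheme: {descriptor.location!r}")
    if known is not None and known.checksum == tag.checksum:
        return UNCHANGED
    return tag


def _retrieve_into(descriptor: SourceDescriptor, target: Path) -> list[tuple[str, int, str]]:
    """Copy or download the payload into ``target``; returns the file manifest."""
    scheme = urlparse(descriptor.location).scheme
    if scheme == "file":
        src = _file_url_path(descriptor.location)
        if src.is_file():
            shutil.copy2(src, target / src.name)
        else:
            for entry in sorted(p for p in src.rglob("*") if p.is_file()):
                rel = entry.relative_to(src)
                dest = target / rel
                dest.parent.mkdir(parents=True, exist_ok=True)
                shutil.copy2(entry, dest)
    else:
        body, _validator = _http_fetch(descriptor.location)
        name = Path(urlparse(descriptor.location).path).name or "payload"
        (target / name).write_bytes(body)
    files = []
    for entry in sorted(p for p in target.rglob("*") if p.is_file()):
        rel = entry.relative_to(target).as_posix()
        files.append((rel, entry.stat().st_size, _sha256_file(entry)))
    return files


def _known_tags(source_dir: Path) -> dict[str, ReleaseTag]:
    """Map checksum -> tag for every release already on disk."""
    tags: dict[str, ReleaseTag] = {}
    if not source_dir.is_dir():
        return tags
    for folder in source_dir.iterdir():
        sidecar = folder / SIDECAR_NAME
        if sidecar.is_file():
            data = json.loads(sidecar.read_text(encoding="utf-8"))
            tags[data["checksum"]] = ReleaseTag(
                value=data["release"], origin=data["origin"], checksum=data["checksum"]
            )
    return tags


def dump_source(
    descriptor: SourceDescriptor,
    data_root: str | Path,
    force: bool = False,
) -> Union[DumpResult, _Skipped]:
    """Retrieve the source into a new release folder, or skip when unchanged.

    The payload is written to a temp folder and renamed into place only after
    its checksums verify, so an interrupted dump leaves the release list
    untouched.  ``force`` re-fetches an unchanged release into its existing
    folder; a changed source always gets a fresh folder.
    """
    data_root = Path(data_root)
    source_dir = data_root / descriptor.name
    current = detect_release(descriptor, None)
    assert isinstance(current, ReleaseTag)
    existing = _known_tags(source_dir)
    if current.checksum in existing:
        if not force:
            return SKIPPED
        current = existing[current.checksum]  # re-fetch into the same folder

    source_dir.mkdir(parents=True, exist_ok=True)
    temp = source_dir / f".tmp-{current.checksum[:12]}"
    if temp.exists():
        shutil.rmtree(temp)
    temp.mkdir()
    try:
        files = _retrieve_into(descriptor, temp)
        scheme = urlparse(descriptor.location).scheme
        is_dir_source = scheme == "file" and _file_url_path(descriptor.location).is_dir()
        if is_dir_source:  # aggregate over sorted (relpath, sha) pairs
            digest = hashlib.sha256()
            for rel, _size, sha in files:
                digest.update(rel.encode())
                digest.update(sha.encode())
            copied_checksum = digest.hexdigest()
        else:
            copied_checksum = files[0][2]
        if copied_checksum != current.checksum:
            raise DumpError(
                f"checksum mismatch after copy for source {descriptor.name!r}"
            )
        sidecar = {
            "release": current.value,
            "origin": current.origin,
            "checksum": current.checksum,
            "retrieved_at": datetime.now(timezone.utc).isoformat(),
            "files": [{"path": p, "bytes": b, "sha256": s} for p, b, s in files],
        }
        (temp / SIDECAR_NAME).write_text(
            json.dumps(sidecar, indent=2), encoding="utf-8"
        )
    except Exception:
        shutil.rmtree(temp, ignore_errors=True)
        raise
    final = source_dir / current.value
    if final.exists():
        shutil.rmtree(final)
    temp.rename(final)
    return DumpResult(
        source=descriptor.name, release=current, files=files, folder=final
    )


def list_local_releases(source: str, data_root: str | Path) -> list[ReleaseTag]:
    """All locally dumped releases of ``source``, ascending by tag value."""
    source_dir = Path(data_root) / source
    tags = list(_known_tags(source_dir).values())
    return sorted(tags, key=lambda t: t.value)


def release_folder(source: str, release_value: str, data_root: str | Path) -> Path:
    return Path(data_root) / source / release_value
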