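"""Dump stage: release detection, atomic versioned retrieval, idempotence."""

from __future__ import annotations

import hashlib
import http.server
import json
import os
import threading
import time

import pytest

import annohub.dump as dump_mod
from annohub import (
    RetrievalError,
    SKIPPED,
    SourceDescriptor,
    UNCHANGED,
    detect_release,
    dump_source,
    list_local_releases,
)
from annohub.errors import DumpError


def file_source(path, name="src"):
    return SourceDescriptor(
        name=name, location=path.resolve().as_uri(), parser_ref="json:loads"
    )


@pytest.fixture()
def payload(tmp_path):
    path = tmp_path / "payload.tsv"
    path.write_text("_id\tv\ng1\t1\n")
    return path


class TestDetectRelease:
    def test_known_tag_with_same_content_is_unchanged(self, payload):
        d = file_source(payload)
        tag = detect_release(d)
        assert detect_release(d, known=tag) is UNCHANGED

    def test_changed_content_yields_new_tag(self, payload):
        d = file_source(payload)
        old = detect_release(d)
        payload.write_text("_id\tv\ng1\t2\n")
        new = detect_release(d, known=old)
        assert new is not UNCHANGED
        # independent recomputation of the content checksum
        assert new.checksum == hashlib.sha256(payload.read_bytes()).hexdigest()
        assert new.checksum != old.checksum

    def test_absent_known_always_returns_a_tag(self, payload):
        d = file_source(payload)
        tag = detect_release(d, known=None)
        assert tag is not UNCHANGED and tag.value

    def test_pure_function_of_content(self, payload):
        d = file_source(payload)
        assert detect_release(d).checksum == detect_release(d).checksum

    def test_unreachable_location_raises(self, tmp_path):
        d = file_source(tmp_path / "missing.tsv")
        with pytest.raises(RetrievalError):
            detect_release(d)

    def test_touched_file_same_content_is_still_unchanged(self, payload):
        # content identity: a bare mtime bump is not a new release
        d = file_source(payload)
        tag = detect_release(d)
        future = time.time() + 10
        os.utime(payload, (future, future))
        assert detect_release(d, known=tag) is UNCHANGED


class TestDumpSource:
    def test_fresh_dump_creates_folder_and_sidecar(self, payload, tmp_path):
        root = tmp_path / "root"
        result = dump_source(file_source(payload), root)
        assert result is not SKIPPED
        assert result.folder.is_dir()
        sidecar = json.loads((result.folder / "release.json").read_text())
        assert sidecar["release"] == result.release.value
        assert len(sidecar["files"]) == 1
        assert sidecar["files"][0]["sha256"] == result.release.checksum

    def test_unchanged_redump_is_skipped(self, payload, tmp_path):
        root = tmp_path / "root"
        d = file_source(payload)
        dump_source(d, root)
        assert dump_source(d, root) is SKIPPED
        assert len(list_local_releases("src", root)) == 1

    def test_force_refetches_into_same_folder(self, payload, tmp_path):
        root = tmp_path / "root"
        d = file_source(payload)
        first = dump_source(d, root)
        forced = dump_source(d, root, force=True)
        assert forced is not SKIPPED
        assert forced.folder == first.folder
        assert len(list_local_releases("src", root)) == 1

    def test_changed_source_gets_new_ascending_release(self, payload, tmp_path):
        root = tmp_path / "root"
        d = file_source(payload)
        for content in ("a\n", "b\n", "c\n"):
            payload.write_text(content)
            now = time.time()
            os.utime(payload, (now, now))
            dump_source(d, root)
            time.sleep(1.05)  # mtime labels have second granularity
        tags = list_local_releases("src", root)
        assert len(tags) == 3
        values = [t.value for t in tags]
        assert values == sorted(values)
        # matches the on-disk folder listing
        folders = sorted(
            p.name for p in (root / "src").iterdir() if (p / "release.json").is_file()
        )
        assert values == folders

    def test_failed_dump_leaves_releases_untouched(self, payload, tmp_path, monkeypatch):
        root = tmp_path / "root"
        d = file_source(payload)
        dump_source(d, root)
        before = [t.value for t in list_local_releases("src", root)]
        payload.write_text("changed\n")

        def explode(*args, **kwargs):
            raise OSError("disk full mid-copy")

        monkeypatch.setattr(dump_mod.shutil, "copy2", explode)
        with pytest.raises(OSError):
            dump_source(d, root)
        after = [t.value for t in list_local_releases("src", root)]
        assert after == before
        assert not any(p.name.startswith(".tmp") for p in (root / "src").iterdir())

    def test_checksum_mismatch_after_copy_raises(self, payload, tmp_path, monkeypatch):
        root = tmp_path / "root"
        d = file_source(payload)
        real = dump_mod._retrieve_into

        def corrupt(descriptor, target):
            files = real(descriptor, target)
            victim = target / files[0][0]
            victim.write_text("corrupted")
            return [(files[0][0], 9, hashlib.sha256(b"corrupted").hexdigest())]

        monkeypatch.setattr(dump_mod, "_retrieve_into", corrupt)
        with pytest.raises(DumpError, match="checksum mismatch"):
            dump_source(d, root)
        assert list_local_releases("src", root) == []

    def test_directory_source_copied_recursively(self, tmp_path):
        src = tmp_path / "srcdir"
        (src / "sub").mkdir(parents=True)
        (src / "a.tsv").write_text("x\n")
        (src / "sub" / "b.tsv").write_text("y\n")
        result = dump_source(file_source(src), tmp_path / "root")
        copied = {rel for rel, _b, _s in result.files}
        assert copied == {"a.tsv", "sub/b.tsv"}

    def test_never_dumped_lists_empty(self, tmp_path):
        assert list_local_releases("ghost", tmp_path) == []


class TestHttpSource:
    @pytest.fixture()
    def http_server(self, tmp_path):
        docroot = tmp_path / "www"
        docroot.mkdir()
        (docroot / "genes.tsv").write_text("_id\tv\ng1\t1\n")
        handler = lambda *a, **kw: http.server.SimpleHTTPRequestHandler(
            *a, directory=str(docroot), **kw
        )
        server = http.server.ThreadingHTTPServer(("127.0.0.1", 0), handler)
        server.RequestHandlerClass.log_message = lambda *a: None
        thread = threading.Thread(target=server.serve_forever, daemon=True)
        thread.start()
        yield f"http://127.0.0.1:{server.server_address[1]}", docroot
        server.shutdown()
        server.server_close()

    def test_http_dump_and_unchanged_detection(self, http_server, tmp_path):
        base, docroot = http_server
        d = SourceDescriptor(
            name="web", location=f"{base}/genes.tsv", parser_ref="json:loads"
        )
        result = dump_source(d, tmp_path / "root")
        assert result is not SKIPPED
        assert (result.folder / "genes.tsv").read_text() == "_id\tv\ng1\t1\n"
        assert dump_source(d, tmp_path / "root") is SKIPPED
        (docroot / "genes.tsv").write_text("_id\tv\ng1\t2\n")
        second = dump_source(d, tmp_path / "root")
        assert second is not SKIPPED
        assert len(list_local_releases("web", tmp_path / "root")) == 2

    def test_http_unreachable_raises(self):
        d = SourceDescriptor(
            name="web", location="http://127.0.0.1:1/none", parser_ref="json:loads"
        )
        with pytest.raises(RetrievalError):
            detect_release(d)
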