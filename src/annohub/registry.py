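"""Plugin registry: load manifests, validate and register data-source plugins.

A data plugin is a directory holding a ``manifest.json`` and, usually, a
``parser.py`` beside it.  The manifest names the source location (``file://``
or ``http(s)://``), the parser entry point (``unit:callable``), an optional
five-field cron schedule, a merge priority and free-form metadata.  One
plugin describes exactly one source.
"""

from __future__ import annotations

import importlib
import importlib.util
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Any, Callable, Optional
from urllib.parse import urlparse

from .cron import fires_between, parse_cron
from .errors import ManifestError, RegistrationError

logger = logging.getLogger(__name__)

NAME_PATTERN = re.compile(r"^[A-Za-z0-9_]+$")
DEFAULT_PRIORITY = 100
ALLOWED_SCHEMES = ("file", "http", "https")


@dataclass
class SourceDescriptor:
    """A registered data-source plugin.

    ``priority`` orders sources in merges (lower = higher precedence); an
    absent ``schedule`` means the source refreshes only on manual trigger.
    """

    name: str
    location: str
    parser_ref: str
    schedule: Optional[str] = None
    priority: int = DEFAULT_PRIORITY
    metadata: dict = field(default_factory=dict)
    plugin_dir: Optional[str] = None  # where parser.py lives, when file-based

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "location": self.location,
            "parser_ref": self.parser_ref,
            "schedule": self.schedule,
            "priority": self.priority,
            "metadata": self.metadata,
            "plugin_dir": self.plugin_dir,
        }

    @classmethod
    def from_json(cls, data: dict) -> "SourceDescriptor":
        return cls(**data)


def load_manifest(path: str | Path) -> SourceDescriptor:
    """Load and validate a plugin manifest, returning a fully defaulted descriptor.

    ``path`` may be the ``manifest.json`` file itself or the plugin directory
    containing it.  Validation reports *all* violations at once; the parser
    entry point is resolved eagerly (fail fast) before the descriptor is
    returned.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    if not path.is_file():
        raise ManifestError([f"manifest not found: {path}"])
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ManifestError([f"manifest is not valid JSON: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ManifestError(["manifest must be a JSON object"])

    violations: list[str] = []
    missing = [key for key in ("name", "location", "parser_ref") if key not in raw]
    if missing:
        violations.append("missing required keys: " + ", ".join(sorted(missing)))

    name = raw.get("name")
    if name is not None and (not isinstance(name, str) or not NAME_PATTERN.match(name)):
        violations.append(f"name must match [A-Za-z0-9_]+: {name!r}")

    location = raw.get("location")
    if location is not None:
        scheme = urlparse(str(location)).scheme
        if scheme not in ALLOWED_SCHEMES:
            violations.append(
                f"location scheme must be one of {ALLOWED_SCHEMES}: {location!r}"
            )

    priority = raw.get("priority", DEFAULT_PRIORITY)
    if not isinstance(priority, int) or isinstance(priority, bool) or priority < 1:
        violations.append(f"priority must be an integer >= 1: {priority!r}")

    schedule = raw.get("schedule")
    if schedule is not None and not isinstance(schedule, str):
        violations.append(f"schedule must be a string cron expression: {schedule!r}")

    metadata = raw.get("metadata", {})
    if not isinstance(metadata, dict):
        violations.append("metadata must be a key/value object")

    if violations:
        raise ManifestError(violations)

    descriptor = SourceDescriptor(
        name=str(name),
        location=str(location),
        parser_ref=str(raw["parser_ref"]),
        schedule=schedule,
        priority=priority,
        metadata=metadata,
        plugin_dir=str(path.parent),
    )
    resolve_parser(descriptor)  # fail fast on unresolvable entry points
    return descriptor


def resolve_parser(descriptor: SourceDescriptor) -> Callable:
    """Resolve ``unit:callable`` to a callable.

    ``unit`` is looked up first as ``<unit>.py`` beside the manifest, then as
    an importable module.  Raises :class:`RegistrationError` naming the entry
    point when it cannot be resolved.
    """
    ref = descriptor.parser_ref
    if ":" not in ref:
        raise RegistrationError(f"parser_ref must be 'unit:callable', got {ref!r}")
    unit, func_name = ref.split(":", 1)
    module = None
    if descriptor.plugin_dir:
        candidate = Path(descriptor.plugin_dir) / f"{unit}.py"
        if candidate.is_file():
            spec = importlib.util.spec_from_file_location(
                f"annohub_plugin_{descriptor.name}_{unit}", candidate
            )
            assert spec and spec.loader
            module = importlib.util.module_from_spec(spec)
            try:
                spec.loader.exec_module(module)
            except Exception as exc:
                raise RegistrationError(
                    f"parser unit {candidate} failed to load: {exc}"
                ) from exc
    if module is None:
        try:
            module = importlib.import_module(unit)
        except ImportError as exc:
            raise RegistrationError(f"unresolvable parser_ref {ref!r}: {exc}") from exc
    func = getattr(module, func_name, None)
    if not callable(func):
        raise RegistrationError(f"unresolvable parser_ref {ref!r}: no callable {func_name!r}")
    return func


def schedule_due(
    descriptor: SourceDescriptor,
    last_run: Optional[datetime],
    now: datetime,
) -> bool:
    """True iff the source's schedule fired at least once in ``(last_run, now]``.

    A source without a schedule is manual-only (never due); a scheduled
    source that never ran is always due.  Pure function of its arguments.
    """
    if descriptor.schedule is None:
        return False
    schedule = parse_cron(descriptor.schedule)  # raises ScheduleError if malformed
    if last_run is None:
        return True
    return fires_between(schedule, last_run, now)


class Registry:
    """In-memory registry of source descriptors plus per-source state.

    State (last dump/upload times, last release, document counts) survives
    re-registration of a plugin; re-registering a name replaces the prior
    descriptor with a warning.
    """

    def __init__(self) -> None:
        self.descriptors: dict[str, SourceDescriptor] = {}
        self.state: dict[str, dict[str, Any]] = {}

    def register(self, descriptor: SourceDescriptor) -> None:
        if descriptor.name in self.descriptors:
            logger.warning("replacing registered source %r", descriptor.name)
        self.descriptors[descriptor.name] = descriptor

    def get(self, name: str) -> Optional[SourceDescriptor]:
        return self.descriptors.get(name)

    def names(self) -> list[str]:
        return sorted(self.descriptors)

    def get_state(self, name: str) -> dict[str, Any]:
        return self.state.setdefault(name, {})

    def save(self, path: str | Path) -> None:
        payload = {
            "descriptors": {n: d.to_json() for n, d in self.descriptors.items()},
            "state": {n: s for n, s in self.state.items() if n in self.descriptors},
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Registry":
        registry = cls()
        path = Path(path)
        if not path.is_file():
            return registry
        payload = json.loads(path.read_text(encoding="utf-8"))
        for name, data in payload.get("descriptors", {}).items():
            registry.descriptors[name] = SourceDescriptor.from_json(data)
        registry.state.update(payload.get("state", {}))
        return registry
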