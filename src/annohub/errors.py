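"""Exception hierarchy for the hub.

Every domain failure derives from :class:`AnnoHubError`; the CLI maps these
to exit code 1 and usage problems to exit code 2.
"""

from __future__ import annotations


class AnnoHubError(Exception):
    """Base class for all hub-domain errors."""


class ManifestError(AnnoHubError):
    """A plugin manifest is missing keys or violates its schema.

    ``violations`` lists every problem at once, never just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid manifest: " + "; ".join(self.violations))


class RegistrationError(AnnoHubError):
    """A plugin could not be registered (e.g. unresolvable parser entry point)."""


class ScheduleError(AnnoHubError):
    """A cron schedule expression is malformed."""


class RetrievalError(AnnoHubError):
    """A source location could not be reached or its payload obtained."""


class DumpError(AnnoHubError):
    """A dump failed after retrieval (checksum mismatch, partial copy)."""


class UploadError(AnnoHubError):
    """The parser raised mid-stream; the target namespace was left untouched."""

    def __init__(self, message: str, last_good_ordinal: int = 0):
        self.last_good_ordinal = last_good_ordinal
        super().__init__(message)


class BuildError(AnnoHubError):
    """A build configuration references unknown sources or unreadable state."""


class QueryParseError(AnnoHubError):
    """A query string could not be parsed; ``position`` is the 0-based offset."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class UnqueryableFieldError(AnnoHubError):
    """A fielded query touched a path outside the index mapping."""

    def __init__(self, path: str, reason: str = "not in the index mapping"):
        self.path = path
        super().__init__(f"unqueryable field {path!r}: {reason}")
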