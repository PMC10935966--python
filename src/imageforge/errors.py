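"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`ForgeError`,
so callers (and the CLI) can catch one type.
"""

from __future__ import annotations


class ForgeError(Exception):
    """Base class for all errors raised by imageforge."""


class ConfigParseError(ForgeError):
    """A configuration file could not be parsed.

    Carries the 1-based line number when one is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PlanValidationError(ForgeError):
    """A build plan or one of its layers failed validation."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations) or "invalid plan")


class ResolutionError(ForgeError):
    """Dependency resolution failed (unknown package, missing version...)."""


class DependencyCycleError(ResolutionError):
    """The dependency graph contains a cycle."""

    def __init__(self, cycle: list[tuple[str, str]]):
        self.cycle = list(cycle)
        names = " -> ".join(f"{eco}:{name}" for name, eco in self.cycle)
        super().__init__(f"dependency cycle: {names}")


class BackendError(ForgeError):
    """The sandbox backend failed mid-capture; carries the partial log."""

    def __init__(self, message: str, log: str = ""):
        self.log = log
        super().__init__(message)


class IntegrityError(ForgeError):
    """A checksum or size check failed (corrupt or missing volume, etc.)."""


class DockerfileParseError(ForgeError):
    """Text handed to the offline-closure scanner is not a Dockerfile."""
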