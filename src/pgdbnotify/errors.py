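"""Exception hierarchy.

Parse and validation failures carry enough context (file, line, row) to be
actionable from the command line; they map to CLI exit code 2.
"""


class PgdbError(Exception):
    """Base class for all package errors."""


class ParseError(PgdbError):
    """Malformed flatfile input; names the offending line."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}:"
        if line is not None:
            loc += f"{line}:"
        super().__init__(f"{loc} {message}" if loc else message)
        self.path = path
        self.line = line


class IntegrityError(PgdbError):
    """Snapshot-level consistency violation (duplicate ids, bad merge provenance)."""


class ValidationError(PgdbError):
    """Invalid domain object (bad subscription kind/mode, bad slot value)."""


class ResolutionError(PgdbError):
    """A referenced object id cannot be resolved in the snapshot."""


class OntologyError(PgdbError):
    """The PARENTS graph of an ontology is not a DAG."""


class ScriptError(PgdbError):
    """An edit script is inconsistent (conflicting edits, missing targets)."""


class ConfigurationError(PgdbError):
    """Bad relation/category configuration or URL template."""
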