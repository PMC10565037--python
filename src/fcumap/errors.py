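"""Exception hierarchy.

Curation failures are *not* exceptions (they are skipped outcomes); these
classes cover contract violations and unreadable inputs only.
"""


class FcumapError(Exception):
    """Base class for all package errors."""


class InvalidNameError(FcumapError):
    """A scientific-name label is empty or unparsable."""


class MissingEntityError(FcumapError, KeyError):
    """A taxon, name or usage IRI does not resolve in the loaded graphs."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return Exception.__str__(self)


class UnknownPredicateError(FcumapError, KeyError):
    """A mapping predicate is not in the registry."""

    def __str__(self) -> str:
        return Exception.__str__(self)


class WrongKindError(FcumapError):
    """An annotation predicate was passed where an object predicate is required
    (or vice versa)."""


class WrongLevelError(FcumapError):
    """A name-level mapping was passed to an operation expecting taxon-level
    mappings (or vice versa)."""


class ConfidenceError(FcumapError, ValueError):
    """Mapping confidence outside [0, 1]."""


class MergeError(FcumapError):
    """Two mapping sets cannot be merged (conflicting CURIE prefix bindings)."""


class UnknownPrefixError(FcumapError, KeyError):
    """CURIE expansion requested for a prefix with no binding."""

    def __str__(self) -> str:
        return Exception.__str__(self)


class LoadError(FcumapError):
    """A knowledge-graph file is unparsable or referentially broken; the
    message names the offending node."""


class FormatError(FcumapError):
    """An SSSOM TSV file lacks the embedded metadata block or is otherwise
    structurally broken."""


class RowError(FormatError):
    """A TSV row is missing a mandatory cell; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class WriteRefusedError(FcumapError):
    """Serialization refused because a mandatory field is missing; the message
    names the field."""


class ParameterError(FcumapError, ValueError):
    """Invalid random-generator parameters."""
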