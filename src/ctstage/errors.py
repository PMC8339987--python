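"""Exception hierarchy shared across the package."""


class CtStageError(Exception):
    """Base class for all package errors."""


class CorruptAnnotationError(CtStageError):
    """A standoff annotation line disagrees with the report text."""


class SchemaViolationError(CtStageError):
    """An annotation violates the entity/relation schema."""


class AnnotationConflictError(CtStageError):
    """Overlapping entity mentions within one sentence."""


class InsufficientDataError(CtStageError):
    """Too little data for the requested operation (e.g. a 3-way split)."""


class DegenerateDataError(CtStageError):
    """Training data does not contain enough label variety."""


class DivergenceError(CtStageError):
    """Training produced a non-finite loss."""


class SizeParseError(CtStageError):
    """A size surface contains no parsable number."""
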