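"""Exception hierarchy for the pipeline.

Every error raised by the library derives from :class:`CopreError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class CopreError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(CopreError):
    """A required column is missing or unresolvable."""


class DuplicateRecordError(CopreError):
    """The same (protein, sample) pair appears more than once."""


class ValidationError(CopreError):
    """An input value violates a documented contract."""


class ConflictError(CopreError):
    """Duplicate identifiers carry contradictory values."""


class EmptyInputError(CopreError):
    """An input file or collection is empty where content is required."""


class MissingLengthError(CopreError):
    """A counted protein has no known length."""


class DegenerateSampleError(CopreError):
    """A sample has no nonzero spectral counts, so NSAF is undefined."""


class PairingError(CopreError):
    """Pulldown and control replicates cannot be paired by index."""


class ContainmentError(CopreError):
    """A foreground/candidate set is not contained in its universe."""


class UndefinedPercentageError(CopreError):
    """A percentage was requested with a zero denominator."""
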