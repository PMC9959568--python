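"""Exception hierarchy shared across the package."""


class OlfmapError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OlfmapError, ValueError):
    """An argument violates a documented precondition."""


class DataError(OlfmapError, ValueError):
    """Input data are malformed or incompletely classified."""


class SchemaError(DataError):
    """A tabular input does not match the documented schema."""


class StateError(OlfmapError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class DegenerateTableError(DataError):
    """A contingency table has an empty margin, so the test is undefined."""


class UndefinedCorrelationError(DataError):
    """Pearson correlation is undefined (zero variance in an input series)."""


class StaircaseIncompleteError(OlfmapError, RuntimeError):
    """The threshold staircase hit its presentation cap before 7 reversals."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
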