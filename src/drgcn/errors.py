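"""Exception types shared across the pipeline."""


class DrgcnError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DrgcnError, ValueError):
    """An input matrix or parameter violates a documented precondition."""


class SchemaError(DrgcnError, ValueError):
    """A tabular input is missing required columns or has malformed rows."""


class AlignmentError(DrgcnError, ValueError):
    """Gene or sample orderings disagree between two inputs that must be aligned."""


class DegenerateNetworkError(DrgcnError, ValueError):
    """The network is too degenerate for the requested operation (e.g. no edges)."""


class ConfigurationError(DrgcnError, ValueError):
    """A model or pipeline configuration is internally inconsistent."""


class UndefinedMetricError(DrgcnError, ValueError):
    """A metric is undefined for the given labels (e.g. a single-class vector)."""
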