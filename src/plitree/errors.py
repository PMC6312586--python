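"""Exception types shared across the pipeline."""


class PlitreeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PlitreeError, ValueError):
    """A configuration value or function argument is out of its valid domain."""


class InvalidInputError(PlitreeError, ValueError):
    """A data object (matrix, vector, recording) violates a structural precondition."""


class InsufficientDataError(PlitreeError, ValueError):
    """A recording is too short (or too masked) for the requested epoching.

    Attributes
    ----------
    found : int
        Number of clean epochs that were actually available.
    requested : int
        Number of epochs that were asked for.
    """

    def __init__(self, message: str, found: int, requested: int):
        super().__init__(message)
        self.found = found
        self.requested = requested


class UndefinedMetricError(PlitreeError, ValueError):
    """A graph metric is degenerate for the given input (e.g. trees with N < 3)."""


class ConfigurationError(PlitreeError, ValueError):
    """A pipeline configuration file or object is invalid."""
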