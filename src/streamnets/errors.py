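"""Exception types shared across the pipeline."""


class StreamnetsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StreamnetsError):
    """A configuration value is invalid or inconsistent."""


class InputError(StreamnetsError):
    """An input table violates its schema or a precondition."""


class UndefinedMetricError(StreamnetsError):
    """A metric is mathematically undefined for the given input."""


class ConvergenceError(StreamnetsError):
    """A model fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CollinearityError(StreamnetsError):
    """Design matrix is rank deficient."""
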