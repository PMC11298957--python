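"""Exception hierarchy for twinpath."""


class TwinpathError(Exception):
    """Base class for all twinpath errors."""


class InsufficientDataError(TwinpathError):
    """Too few twin pairs (or donors) for the requested computation."""


class DegenerateDataError(TwinpathError):
    """Zero variance or otherwise degenerate input."""


class ConvergenceError(TwinpathError):
    """Optimiser failed to converge; carries the best candidate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class NestingError(TwinpathError):
    """Model comparison requested for non-nested specifications."""


class ParseError(TwinpathError):
    """Malformed input file."""


class ConfigError(TwinpathError):
    """Invalid configuration or simulation truth."""
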