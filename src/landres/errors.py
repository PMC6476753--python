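"""Exception hierarchy for landres.

Every error raised by the library derives from :class:`LandresError`, so
callers (and the CLI) can distinguish input problems from internal bugs.
"""


class LandresError(Exception):
    """Base class for all landres errors."""


class ConfigurationError(LandresError):
    """Invalid configuration values (dimensions, proportions, weights ...)."""


class GenerationError(LandresError):
    """Synthetic-data generation could not satisfy its contract."""


class ParseError(LandresError):
    """A file could not be parsed; message carries the offending line."""


class EncodingError(LandresError):
    """Data cannot be represented in the requested output format."""


class DegenerateMatrixError(LandresError):
    """A distance matrix has zero variance where a statistic needs some."""


class CollinearityError(LandresError):
    """Conditioning matrix perfectly correlated with a test matrix."""
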