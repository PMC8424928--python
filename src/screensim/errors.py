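"""Exception hierarchy shared across the package."""


class ScreensimError(Exception):
    """Base class for all package errors."""


class ParameterError(ScreensimError, ValueError):
    """A distribution or model parameter is outside its domain."""


class ConfigError(ScreensimError, ValueError):
    """A scenario/model configuration document is malformed.

    The message carries a dotted path into the document (e.g. ``routes.X1``)
    so the offending entry can be located.
    """


class InsufficientDataError(ScreensimError, ValueError):
    """Too few observations for the requested estimation."""


class DegenerateDataError(ScreensimError, ValueError):
    """Observations carry no usable variation (e.g. zero variance)."""


class ModelConsistencyError(ScreensimError, RuntimeError):
    """The simulation reached a state the model forbids (wrong-sex station,
    entity stranded at a permanently closed station, ...)."""
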