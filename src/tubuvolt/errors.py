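"""Exception hierarchy.

Every error the library raises derives from :class:`TubuvoltError` so callers
can catch the whole family; the leaves also derive from the closest builtin
(`ValueError`, `RuntimeError`) so idiomatic handling keeps working.
"""


class TubuvoltError(Exception):
    """Base class for all tubuvolt errors."""


class InputFormatError(TubuvoltError, ValueError):
    """A delimited-text input file is malformed (message names the line)."""


class GeometryError(TubuvoltError, ValueError):
    """A potential window or segment selection contains no samples."""


class DomainError(TubuvoltError, ValueError):
    """An argument is outside the mathematical domain of an estimator."""


class ConfigurationError(TubuvoltError, ValueError):
    """Inconsistent or invalid configuration (message carries the path/key)."""


class ConvergenceError(TubuvoltError, RuntimeError):
    """A stochastic walk failed to terminate within the step cap."""


class StateError(TubuvoltError, RuntimeError):
    """An operation was applied to an object in the wrong state."""


class ResolutionError(TubuvoltError, ValueError):
    """A sampling interval is too coarse for the requested waveform."""
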