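"""Exception hierarchy for spcdrift.

All domain errors derive from :class:`SpcDriftError` so callers can catch the
package's failures with a single except clause; each subclass marks one
contract violation described in the module that raises it.
"""


class SpcDriftError(Exception):
    """Base class for all spcdrift errors."""


class ParameterError(SpcDriftError, ValueError):
    """An invalid parameter value (non-positive scale, bad rate interval ...)."""


class ConfigurationError(SpcDriftError, ValueError):
    """Inconsistent configuration, e.g. labels missing for a supervised fit."""


class NotFittedError(SpcDriftError, RuntimeError):
    """An extractor was used before :func:`fit_extractor`."""


class ZeroVectorError(SpcDriftError, ValueError):
    """Cosine similarity requested for a zero-magnitude vector."""


class DegenerateProfileError(SpcDriftError, ValueError):
    """All reference metrics identical: metric_std = 0, control limits undefined."""


class ShapeError(SpcDriftError, ValueError):
    """Dimension mismatch between a vector and a fitted profile."""


class InputError(SpcDriftError, ValueError):
    """A non-finite or structurally invalid chart input."""


class GapError(SpcDriftError, ValueError):
    """A day inside the monitored range has no records."""


class UndefinedStatisticError(SpcDriftError, ValueError):
    """A confusion-matrix statistic is undefined because a truth class is absent."""
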