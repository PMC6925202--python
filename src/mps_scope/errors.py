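"""Exception hierarchy.

All package errors derive from :class:`MPSScopeError` so callers can catch one
base class; parameter/format errors additionally derive from ``ValueError``.
"""


class MPSScopeError(Exception):
    """Base class for all mps-scope errors."""


class ParameterError(MPSScopeError, ValueError):
    """Invalid parameter value (non-positive period, min > max, ...)."""


class FormatError(MPSScopeError, ValueError):
    """Malformed localization file: missing columns or unparseable cells."""


class PeakNotFoundError(MPSScopeError):
    """No interior local maximum in the spacing search window.

    Raised e.g. for profiles without periodicity, where an autocorrelation
    curve decays monotonically and no spacing can be reported.
    """


class UndefinedStatisticError(MPSScopeError):
    """Statistic undefined for the input (zero-variance profile)."""


class NoRidgeError(MPSScopeError):
    """A width cut found no intensity peak above the local background."""


class ProtocolError(MPSScopeError, ValueError):
    """Measurement protocol violated (e.g. a line set without five lines)."""


class DegenerateControlPointsError(MPSScopeError, ValueError):
    """Control points collinear or duplicated: affine fit is rank-deficient."""


class TraceOutsideImageError(MPSScopeError, ValueError):
    """A tracing (after band expansion) leaves the image bounds."""
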