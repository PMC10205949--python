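"""Exception types shared across the package."""


class ExtravakitError(Exception):
    """Base class for all package-specific errors."""


class SessionFormatError(ExtravakitError, ValueError):
    """A curve file, dose-factor table or metadata mapping is malformed."""


class CurveValidationError(ExtravakitError, ValueError):
    """A dose-rate curve violates a structural invariant (monotone times, ...)."""


class PlateauNotReachedError(ExtravakitError, RuntimeError):
    """The 60-s stability condition is never satisfied within the record.

    Downstream callers should treat the administration as indeterminate:
    no plateau mean, and therefore no peak-drop or arm-difference metric,
    can be reported.
    """


class FitError(ExtravakitError, RuntimeError):
    """A curve or threshold fit failed to converge or is degenerate."""
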