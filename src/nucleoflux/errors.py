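"""Exception hierarchy shared across the package."""


class NucleofluxError(Exception):
    """Base class for all package errors."""


class PlateFormatError(NucleofluxError):
    """Raised when an input file does not conform to the expected dialect."""


class ValidationError(NucleofluxError):
    """Raised when values parse but violate a domain invariant."""


class CorrectionError(NucleofluxError):
    """Raised when a correction step cannot proceed (e.g. no reference wells)."""


class KineticsError(NucleofluxError):
    """Raised when an activity/synthesis estimate cannot be computed."""


class InductionError(NucleofluxError):
    """Raised when the induction-response window is unusable."""
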