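"""Exception hierarchy.

``CorpusimError`` is the common base; ``InputError`` subclasses indicate bad
user input (CLI exit code 2) while ``NumericalError`` subclasses indicate a
computation that could not be completed (CLI exit code 1).
"""


class CorpusimError(Exception):
    """Base class for all package errors."""


class InputError(CorpusimError):
    """Invalid user-supplied input (file, record, argument)."""


class ValidationError(InputError):
    """A record or table failed validation."""


class GeometryError(InputError):
    """A layered geometry cannot be constructed or is inconsistent."""


class NumericalError(CorpusimError):
    """A numerical procedure failed."""


class IntegrationError(NumericalError):
    """Membrane integration produced non-finite state."""


class CalibrationError(NumericalError):
    """Calibration target is outside the achievable range."""


class NonMonotoneError(NumericalError):
    """A pre-scan violated the monotonicity premise of a bisection search."""


class NoDetectableBandError(NumericalError):
    """A tuning curve contains no detectable thresholds."""
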