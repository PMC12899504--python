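"""Exception hierarchy for the foot-contact detection toolkit."""


class FootContactError(Exception):
    """Base class for all package errors."""


class FormatError(FootContactError, ValueError):
    """Malformed on-disk data (bad header, non-uniform time base, NaNs)."""


class ParameterError(FootContactError, ValueError):
    """A parameter outside its valid range (e.g. cutoff above Nyquist)."""


class SignalLengthError(FootContactError, ValueError):
    """Signal too short for the requested operation."""


class TimeRangeError(FootContactError, ValueError):
    """A time outside the span of the signal it is mapped onto."""


class NoContactError(FootContactError):
    """The force signal never exceeds the contact threshold."""


class TruncatedContactError(FootContactError):
    """A contact starts but never ends within the recorded signal."""


class SelectionError(FootContactError, ValueError):
    """Valid-step selection called on an empty candidate list."""


class InsufficientDataError(FootContactError, ValueError):
    """Too few records for the requested statistic."""


class ModelError(FootContactError, ValueError):
    """Singular or otherwise unfittable statistical model."""


class UndefinedCorrelationError(FootContactError, ValueError):
    """Correlation requested on a zero-variance vector."""


class GenerationError(FootContactError, ValueError):
    """Synthetic-trial specification is infeasible."""
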