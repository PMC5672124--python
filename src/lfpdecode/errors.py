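"""Exception hierarchy shared across the package.

Everything derives from :class:`LfpDecodeError` so callers can catch one
base class; most also derive from the matching builtin (``ValueError`` /
``RuntimeError``) so generic handling keeps working.
"""


class LfpDecodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LfpDecodeError, ValueError):
    """An invalid configuration value; the message names the field."""


class SamplingRateError(LfpDecodeError, ValueError):
    """Sampling rate incompatible with the requested operation."""


class SignalLengthError(LfpDecodeError, ValueError):
    """Signal too short (or shape-mismatched) for the operation."""


class BoundaryError(LfpDecodeError, ValueError):
    """An epoch window falls outside the recording; names the event."""


class EpochExcludedError(LfpDecodeError, ValueError):
    """Feature extraction was attempted on an excluded epoch."""


class DegenerateTrainingError(LfpDecodeError, ValueError):
    """Training data does not contain both classes."""


class SizeError(LfpDecodeError, ValueError):
    """Too few samples for a resampling operation."""


class UndefinedMetricError(LfpDecodeError, ArithmeticError):
    """A metric's denominator is zero; carries a reason code.

    Metrics are never silently imputed as 0 — callers either propagate
    this signal or record the reason in a report.
    """

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        self.reason = reason
        super().__init__(f"{metric} undefined: {reason}")


class ModelStateError(LfpDecodeError, RuntimeError):
    """An untrained or inconsistent model was used for prediction."""


class FileFormatError(LfpDecodeError, ValueError):
    """A malformed on-disk container; message carries line/field context."""
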