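"""Exception hierarchy.

Two broad families map onto the CLI exit codes: :class:`ConfigError` (exit 2,
the request itself is malformed) and :class:`DataError` (exit 3, the request is
fine but the data cannot support it).
"""


class MegfixError(Exception):
    """Base class for all package errors."""


class ConfigError(MegfixError):
    """Invalid configuration, parameters, or architecture request."""


class DataError(MegfixError):
    """Input data violates a precondition of the requested operation."""


class InvalidLayoutError(ConfigError):
    """Sensor-layout request cannot be satisfied (e.g. odd channel count)."""


class InvalidConfigError(ConfigError):
    """Simulation or run configuration violates an invariant."""


class InvalidFilterError(ConfigError):
    """Filter cutoff incompatible with the sampling rate."""


class InvalidRateError(ConfigError):
    """Requested resampling rate is not an integer divisor of the input rate."""


class WindowError(ConfigError):
    """Requested crop window lies outside the stored epoch window."""


class InvalidArchitectureError(ConfigError):
    """Model dimensions are inconsistent (e.g. filter longer than the epoch)."""


class MalformedLogError(DataError):
    """Gaze event log is unordered or contains overlapping events."""


class InsufficientDataError(DataError):
    """Too few trials / classes / participants for the requested computation."""


class DegenerateTrialError(DataError):
    """A trial is constant and cannot be normalized."""


class DegenerateTrainingError(DataError):
    """Training set contains a single class."""


class UndefinedAUCError(DataError):
    """ROC AUC is undefined because only one class is present."""


class UndefinedWeightsError(DataError):
    """All output weights for the requested class are zero."""


class DegenerateLatentsWarning(UserWarning):
    """Latent covariance is (near-)rank-deficient; pseudo-inverse used."""
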