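"""Typed exceptions with stable CLI exit codes.

Exit-code contract: 0 success, 2 configuration error, 3 data error,
4 insufficient sample size.
"""


class FlimColocError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigError(FlimColocError):
    """Invalid or inconsistent configuration."""

    exit_code = 2


class DataError(FlimColocError):
    """Invalid, unreadable, or out-of-contract input data."""

    exit_code = 3


class SampleSizeError(FlimColocError):
    """Too few cells/replicates for the requested analysis."""

    exit_code = 4


class OutOfWindowError(DataError):
    """A photon micro-time falls outside the repetition window."""


class InsufficientPhotonsError(DataError):
    """A decay histogram does not meet the photon-count threshold."""


class ZeroVarianceError(DataError):
    """A channel is constant within the analysis mask."""


class UndefinedCoefficientError(DataError):
    """A co-localization coefficient has a zero denominator."""


class ChannelError(DataError):
    """A requested image channel does not exist."""


class RegridRequiredError(DataError):
    """A measured IRF is sampled on a grid incompatible with the data."""


class PlacementError(ConfigError):
    """Synthetic nuclei cannot be placed without overlap at the
    requested density; lower n_nuclei or enlarge the field."""


class UndefinedMeanError(DataError):
    """Mean lifetime is undefined (all amplitudes zero)."""


class IdentifiabilityWarning(UserWarning):
    """Multi-exponential components too close in lifetime to separate
    reliably (adjacent ratio below 1.5)."""
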