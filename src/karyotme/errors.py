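"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: ConfigError -> 2, DataError (and subclasses)
-> 3, DegenerateDataError -> 4, anything else -> 1.
"""


class KaryoTMEError(Exception):
    """Base class for all package errors."""


class ConfigError(KaryoTMEError):
    """Invalid configuration: bad thresholds, inconsistent options."""


class DataError(KaryoTMEError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """A file does not conform to its expected on-disk format."""


class DegenerateDataError(KaryoTMEError):
    """Statistically degenerate input: constant outcome, empty strata, etc."""
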