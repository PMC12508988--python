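"""Exception hierarchy shared by all helixfit modules."""


class HelixFitError(Exception):
    """Base class for all errors raised by helixfit."""


class DomainError(HelixFitError, ValueError):
    """Model evaluated outside its mathematical domain (e.g. T <= t0)."""


class ConfigError(HelixFitError, ValueError):
    """Invalid configuration: bad units, missing chain length, bad bounds."""


class DataFormatError(HelixFitError, ValueError):
    """Input file does not conform to the two-column, header-free layout."""


class HeaderDetectedError(DataFormatError):
    """First row of an input file is non-numeric; data files must not have headers."""


class InsufficientDataError(DataFormatError):
    """Fewer than the minimum number of usable data rows."""


class NotNormalizedError(DataFormatError):
    """CD values are grossly outside [0, 1]; helicity must be normalized upstream."""


class FitError(HelixFitError, RuntimeError):
    """The least-squares fit could not be completed.

    The usual remedy is to inspect the data (units, baseline subtraction,
    normalization) and correct the source of the error.
    """


class RootNotFoundError(HelixFitError, RuntimeError):
    """No melting midpoint (helicity = 1/2 crossing) inside the search window."""
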