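"""Exception types raised across the pipeline.

All inherit from :class:`CisqpcrError` so callers can catch the package's
failures with a single except clause; each also inherits the closest builtin
(ValueError for bad numeric input, KeyError-ish lookups stay ValueError for
consistency with pandas-style APIs).
"""


class CisqpcrError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CisqpcrError, ValueError):
    """A numeric precondition was violated (negative concentration, empty data...)."""


class MissingCalibrationError(CisqpcrError, ValueError):
    """No usable external-standard well: quantification must not proceed silently."""


class ReferenceFailureError(CisqpcrError, ValueError):
    """The reference gene could not be quantified; the sample is not reportable."""


class ConfigurationError(CisqpcrError, ValueError):
    """Inconsistent run configuration (unknown mixture, empty catalog, bad gene list)."""


class LoadError(CisqpcrError, ValueError):
    """An input file failed validation; the message carries the offending row."""


class DegenerateFitError(CisqpcrError, ValueError):
    """A regression or likelihood fit has no information (identical x values etc.)."""
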