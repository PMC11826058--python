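"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors exit 2 (click's default),
:class:`DataQualityError` and its siblings exit 3, :class:`FitFailureError`
exits 4.
"""


class ExfracError(Exception):
    """Base class for all package errors."""


class FormatError(ExfracError):
    """Input file does not conform to the tidy CSV dialect (e.g. missing column)."""


class DuplicationError(FormatError):
    """Duplicate (well, time) row in a data file."""


class OrderingError(FormatError):
    """Time values within a well are not strictly increasing."""


class DataQualityError(ExfracError):
    """Data are well-formed but unusable (e.g. blank-corrected OD entirely <= 0)."""


class InsufficientDataError(DataQualityError):
    """Too few points / replicates / concentrations for the requested operation."""


class AggregationError(ExfracError):
    """Inconsistent aggregation request (e.g. duplicate concentration entries)."""


class FitFailureError(ExfracError):
    """A model fit failed to converge from every start."""
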