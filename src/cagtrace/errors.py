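"""Exception hierarchy for cagtrace.

Every error raised by the library derives from :class:`CagtraceError` so callers
can catch pipeline failures without masking programming errors.
"""


class CagtraceError(Exception):
    """Base class for all cagtrace errors."""


class ConfigurationError(CagtraceError):
    """A cohort or analysis configuration violates its invariants."""


class FormatError(CagtraceError):
    """A delimited input file is malformed (missing column, bad number)."""


class EmptyTableError(CagtraceError):
    """A peak-table file contains a header but no peaks."""


class CalibrationError(CagtraceError):
    """A fragment size maps to a non-positive repeat count."""


class EmptyDistributionError(CagtraceError):
    """All peaks were filtered out; no repeat distribution remains."""


class PeakFitError(CagtraceError):
    """The iterative Gaussian fit did not converge.

    Carries the best iterate reached so callers can inspect or reuse it.
    """

    def __init__(self, message, best_fits=None):
        super().__init__(message)
        self.best_fits = best_fits


class MissingReferenceError(CagtraceError):
    """No inherited-allele reference is available for an animal."""


class InsufficientDataError(CagtraceError):
    """Fewer observations than the operation's minimum."""


class DesignError(CagtraceError):
    """A regression design matrix is rank deficient or single-stratum."""


class CoverageError(CagtraceError):
    """A reference group required for a comparison is missing."""


class MissingDataError(CagtraceError):
    """Requested records (e.g. a rotarod speed) are absent."""


class UndefinedStatisticError(CagtraceError):
    """A statistic is undefined for the input (e.g. Z with both SEs zero)."""
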