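"""Exception hierarchy for cellelast.

Every error raised by the package derives from :class:`CellElastError`
so callers can catch the package's failures with a single clause.
"""


class CellElastError(Exception):
    """Base class for all cellelast errors."""


class FormatError(CellElastError):
    """A file does not conform to the declared tabular dialect."""


class ValidationError(CellElastError):
    """A data record violates one of its invariants."""


class ParameterError(CellElastError):
    """A function argument is outside its documented domain."""


class CalibrationError(CellElastError):
    """Calibration cannot be computed from the supplied data."""


class ContactDetectionError(CellElastError):
    """No contact point can be located on a force curve."""


class NormalizationError(CellElastError):
    """Plate-reader normalization is impossible (untreated <= blank)."""


class QCError(CellElastError):
    """Too few fits to run the point-stiffness quality control."""


class DegenerateDesignError(CellElastError):
    """Regression design matrix is singular (e.g. all moduli equal)."""


class ConfigError(CellElastError):
    """A synthetic-data configuration is internally inconsistent."""
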