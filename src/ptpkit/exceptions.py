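"""Exception hierarchy for ptpkit.

All package errors derive from :class:`PtpkitError` so callers can catch one
base class; format- and fit-specific subclasses carry more context.
"""


class PtpkitError(Exception):
    """Base class for all ptpkit errors."""


class FormatError(PtpkitError):
    """A file does not conform to the expected text format."""


class AlignmentLengthError(FormatError):
    """Sequences in an alignment do not share a single length."""


class TopologyMismatchError(PtpkitError):
    """Models of a trajectory do not share one atom topology."""


class SelectionError(PtpkitError):
    """A requested chain/residue/atom is absent from a structure."""


class ParameterError(PtpkitError, ValueError):
    """An argument violates a documented precondition."""


class ConstructionError(PtpkitError):
    """A requested synthetic geometry is not realizable."""


class ComputationError(PtpkitError):
    """A structural quantity cannot be computed (e.g. missing backbone atom)."""


class FitError(PtpkitError):
    """A nonlinear or linear fit failed to converge or is ill-posed."""


class FitWarning(UserWarning):
    """A fit succeeded but with a caveat (e.g. one-limb bell fallback)."""


class CoverageError(PtpkitError):
    """An analysis sphere does not intersect the scalar grid."""


class UndefinedResultError(PtpkitError):
    """A statistic is undefined for the given input (e.g. all-gap overlap)."""


class ConfigError(PtpkitError):
    """A configuration file entry is missing or invalid."""
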