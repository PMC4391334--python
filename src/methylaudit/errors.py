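"""Exception hierarchy for methylaudit.

All package-specific errors derive from :class:`MethylAuditError` so callers
can catch one base class. Format/parse problems map to CLI exit code 2.
"""


class MethylAuditError(Exception):
    """Base class for all methylaudit errors."""


class BetaParseError(MethylAuditError):
    """A cell could not be parsed as a number or a recognized missing token."""


class BetaDomainError(MethylAuditError):
    """A beta value lies outside [0, 1]."""


class MatrixFormatError(MethylAuditError):
    """Structural problem in a tabular input (duplicate IDs, bad header...)."""


class AnnotationError(MethylAuditError):
    """A probe annotation row violates its invariants."""


class UnknownIDError(MethylAuditError, KeyError):
    """A probe or sample identifier was not found in a matrix."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return Exception.__str__(self)


class UndefinedStatisticError(MethylAuditError):
    """A statistic was requested on zero observations."""


class InsufficientDataError(MethylAuditError):
    """Not enough shared observations for a comparison."""


class InsufficientVarianceError(MethylAuditError):
    """A correlation was requested on a constant column."""


class InsufficientOverlapError(MethylAuditError):
    """Two fingerprints share no usable loci."""


class DegenerateLocusError(MethylAuditError):
    """An allele frequency of exactly 0 or 1 makes a locus uninformative."""


class ConfigurationError(MethylAuditError):
    """A user-supplied parameter is missing or invalid."""


class SequenceError(MethylAuditError):
    """A nucleotide sequence contains characters outside A/C/G/T."""


class AssayDesignError(MethylAuditError):
    """A digest assay cannot be constructed (e.g. no recognition site)."""
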