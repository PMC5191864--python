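"""Exception hierarchy for mtburden.

Every error raised by the package derives from :class:`MtBurdenError` so that
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class MtBurdenError(Exception):
    """Base class for all package errors."""


class CoordinateError(MtBurdenError):
    """A position falls outside the 1..16569 mitochondrial coordinate range."""


class ReferenceMismatchError(MtBurdenError):
    """A supplied reference base disagrees with the packaged rCRS sequence."""


class AlphabetError(MtBurdenError):
    """A base is not one of A, C, G, T."""


class ConfigError(MtBurdenError):
    """A configuration value is outside its documented domain."""


class DegenerateCohortError(ConfigError):
    """Fewer than two patients requested from the simulator."""


class CountError(MtBurdenError):
    """Inconsistent read counts (alt count exceeding total count)."""


class IncompletePairError(MtBurdenError):
    """A tumor-normal pair is missing an allele frequency on one side."""


class DuplicateCallError(MtBurdenError):
    """The same (patient, position, ref, alt) row appears more than once."""


class EmptySetError(MtBurdenError):
    """An operation that needs at least one observation received none."""


class PurityDomainError(MtBurdenError):
    """Tumor purity outside (0, 1]."""


class JoinError(MtBurdenError):
    """Patient identifiers fail to join across tables."""


class DegeneratePartitionError(MtBurdenError):
    """A genome partition class has zero length."""


class StatsDomainError(MtBurdenError):
    """A statistical routine received arguments outside its domain."""


class RankDeficiencyError(StatsDomainError):
    """Regression predictor is constant."""


class GroupingError(StatsDomainError):
    """Survival comparison requires exactly two non-empty groups."""


class DegenerateLabelError(StatsDomainError):
    """Binary labels contain only one class."""


class PairingError(StatsDomainError):
    """Paired score vectors have mismatched lengths."""


class DegenerateTableError(StatsDomainError):
    """A contingency table is all zeros or otherwise degenerate."""


class InsufficientDataError(MtBurdenError):
    """A clinical record lacks both a relapse flag and a PSA series."""


class ValidationError(MtBurdenError):
    """Input validation failed (CLI exit code 2)."""
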