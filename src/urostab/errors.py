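"""Exception hierarchy used across the package.

All package-specific failures derive from :class:`UrostabError` so callers can
catch one base class at pipeline boundaries.
"""


class UrostabError(Exception):
    """Base class for all urostab errors."""


class TableFormatError(UrostabError):
    """A count-table file could not be parsed (bad cell, bad header, ...)."""


class TableValidationError(UrostabError):
    """A parsed table violates the count-table contract (duplicates, negatives)."""


class MetadataError(UrostabError):
    """Sample/subject metadata is malformed or has invalid levels."""


class PairingError(MetadataError):
    """A subject does not have exactly one sample per timepoint."""


class ReconciliationError(UrostabError):
    """Sample ids in metadata and count table do not match."""


class EmptyCohortError(UrostabError):
    """An operation that requires at least one subject received none."""


class UndefinedStatisticError(UrostabError):
    """A statistic is undefined for the given input (e.g. all-zero vector)."""


class NormalizationError(UrostabError):
    """Relative-abundance normalization failed (zero-read sample)."""


class InsufficientDepthError(UrostabError):
    """A sample has fewer reads than the requested rarefaction depth."""


class AlignmentError(UrostabError):
    """Two abundance vectors do not share a common OTU index."""


class DesignError(UrostabError):
    """A model design matrix is invalid (confounded, constant, rank-deficient)."""


class DegenerateTestError(UrostabError):
    """A hypothesis test has no information (e.g. all paired differences zero)."""


class ConfigError(UrostabError):
    """A configuration object is invalid or infeasible."""
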