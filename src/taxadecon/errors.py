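"""Exception hierarchy.

Every error raised by this package derives from :class:`TaxadeconError`, so
callers can catch the whole family at a pipeline boundary while still
discriminating validation problems from numerical ones.
"""


class TaxadeconError(Exception):
    """Base class for all package errors."""


class TableFormatError(TaxadeconError, ValueError):
    """Structural problem in a table: duplicate ids, non-numeric cells."""


class TableValidationError(TaxadeconError, ValueError):
    """A table parsed but violates a domain invariant (negatives, NaNs)."""


class AlignmentError(TaxadeconError, ValueError):
    """Two tables cannot be aligned on a shared id axis."""


class ParameterError(TaxadeconError, ValueError):
    """An operation was called with an out-of-domain parameter."""


class DegenerateSampleError(TaxadeconError, ValueError):
    """A sample lost all its signal (all-zero row, every taxon cut)."""


class FilterError(TaxadeconError, ValueError):
    """A filtering step removed everything."""


class NormalizationError(TaxadeconError, ValueError):
    """Constant-element normalization is impossible (no usable samples)."""


class DimensionError(TaxadeconError, ValueError):
    """The regression system is underdetermined for the chosen method."""


class SolverError(TaxadeconError, RuntimeError):
    """The linear system is rank-deficient or otherwise unsolvable."""


class SelectionError(TaxadeconError, ValueError):
    """Constant-element selection matched no candidates."""


class MappingError(TaxadeconError, KeyError):
    """Required reference entries (e.g. lengths) are missing for some ids."""


class UndefinedStatisticError(TaxadeconError, ValueError):
    """A requested statistic is undefined on this input (e.g. one-class AUC)."""
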