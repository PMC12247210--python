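"""Exception hierarchy.

Errors are split by who can fix them: ``ConfigurationError`` (caller passed
an inconsistent configuration), ``ValidationError`` (a value violates a
domain invariant), ``InputError`` (a file is unusable as a whole), and
``AnalysisError`` / ``EstimationError`` (the data cannot support the
requested analysis).
"""


class MRPathError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRPathError):
    """Inconsistent or incomplete configuration supplied by the caller."""


class ValidationError(MRPathError):
    """A value violates a domain invariant (bad allele, se <= 0, ...)."""


class InputError(MRPathError):
    """An input file is unusable as a whole (empty, missing columns, ...)."""


class AnalysisError(MRPathError):
    """The data cannot support the requested analysis step."""


class EstimationError(AnalysisError):
    """An estimator's preconditions are not met (too few SNPs, ...)."""
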