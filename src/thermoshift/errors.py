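"""Exception hierarchy shared across the package."""


class ThermoshiftError(Exception):
    """Base class for all package errors."""


class ParseError(ThermoshiftError):
    """Malformed plate CSV, layout document, or FASTA input."""


class ValidationError(ThermoshiftError):
    """An input violates a documented invariant (bad grid, negative
    concentration, duplicate well, ...)."""


class DegenerateFitError(ThermoshiftError):
    """The data carry no usable signal for the requested fit (e.g. all
    dTm values are zero, or no stabilization exists to suppress)."""


class FitNonConvergence(ThermoshiftError):
    """The optimizer failed to converge and no fallback result exists."""


class WorkflowError(ThermoshiftError):
    """An end-to-end workflow cannot proceed (all wells QC-failed,
    missing reference group, ...)."""
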