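"""Typed error hierarchy.

Every error path in the library raises one of these so callers can
distinguish bad input data from degenerate-but-valid data and from
numerical failures.
"""


class KneeOAError(Exception):
    """Base class for all package errors."""


class FormatError(KneeOAError):
    """A file could not be parsed into the expected schema."""


class ValidationError(KneeOAError):
    """Input data violates a domain invariant (bad dosage, negative count...)."""


class DegenerateInputError(KneeOAError):
    """Input is well-formed but the requested statistic is undefined on it
    (single class, empty stratum, zero total)."""


class ConvergenceError(KneeOAError):
    """A maximum-likelihood fit failed to converge or separated."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class GenerationError(KneeOAError):
    """The synthetic-cohort generator could not satisfy the request."""


class SamplingError(KneeOAError):
    """Matched-control resampling could not fill a stratum quota."""
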