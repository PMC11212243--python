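"""Exception hierarchy for mdprio."""


class MdprioError(Exception):
    """Base class for all mdprio errors."""


class InvalidGenotypeError(MdprioError):
    """Allele count inconsistent with a diploid cohort of the stated size."""


class AnnotationError(MdprioError):
    """A variant record is missing a required annotation."""


class ConsistencyError(MdprioError):
    """Inputs that must be successive subsets (or otherwise mutually
    consistent) are not."""


class ConvergenceError(MdprioError):
    """Iterative propagation failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CoverageError(MdprioError):
    """Observed and null score maps do not cover the same gene universe."""
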