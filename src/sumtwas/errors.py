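"""Exception hierarchy for the sumtwas pipeline."""


class SumTwasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SumTwasError, ValueError):
    """A simulation or analysis configuration is invalid."""


class InputError(SumTwasError, ValueError):
    """User-supplied data violates a precondition (bad p-values, missing columns...)."""


class UntestableGeneError(SumTwasError, RuntimeError):
    """The gene cannot be tested (no usable weights, degenerate variance...)."""


class DegenerateVarianceError(UntestableGeneError):
    """The quadratic form W·S·Wt is numerically zero, so z_twas is undefined."""


class NoOverlappingSnpsError(InputError):
    """Weight set and GWAS summary share no SNP identifiers."""
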