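"""Exception hierarchy."""


class PrsConcordError(Exception):
    """Base class for all package errors."""


class FormatError(PrsConcordError):
    """A file could not be parsed (missing column, bad value, duplicate key)."""


class ValidationError(PrsConcordError):
    """An in-memory object violates one of its invariants."""


class ConfigurationError(PrsConcordError):
    """A simulation or pipeline configuration is invalid."""


class FitError(PrsConcordError):
    """A model fit failed (non-convergence, separation, empty stratum)."""


class PipelineError(PrsConcordError):
    """A pipeline stage failed; message names the stage and the cause."""
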