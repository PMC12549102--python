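"""Exception hierarchy shared across the pipeline stages."""


class FetalCwasError(Exception):
    """Base class for all package-specific errors."""


class SpecError(FetalCwasError, ValueError):
    """A simulation or run specification is internally inconsistent."""


class InputError(FetalCwasError, ValueError):
    """An input array/table violates a structural precondition."""


class DesignError(FetalCwasError, ValueError):
    """A regression design matrix is unusable (rank deficient, no intercept)."""


class ScoreRangeError(FetalCwasError, ValueError):
    """A questionnaire score lies outside its instrument's admissible range."""


class DegenerateInputError(FetalCwasError, ValueError):
    """Statistically degenerate input (constant series, zero variance)."""


class PipelineError(FetalCwasError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
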