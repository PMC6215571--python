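"""Exception hierarchy for the dabquant pipeline.

All errors derive from :class:`DabquantError` so that the pipeline driver can
catch domain failures (and exclude the offending sample with a recorded
reason) without swallowing programming errors.
"""


class DabquantError(Exception):
    """Base class for all domain errors raised by dabquant."""


class InvalidSlideSpecError(DabquantError, ValueError):
    """A synthetic slide specification violates its physical invariants."""


class InvalidReferenceError(DabquantError, ValueError):
    """A background (incident light) reference is non-positive or out of range."""


class DegenerateStainBasisError(DabquantError, ValueError):
    """The stain matrix is singular or too ill-conditioned to invert."""


class InvalidROIError(DabquantError, ValueError):
    """A region-of-interest polygon is degenerate, empty, or inconsistent."""


class MissingMeasurementError(DabquantError, ValueError):
    """A required measurement list (e.g. mucosal heights) is empty."""


class InvalidNormalizerError(DabquantError, ValueError):
    """A per-length normalizer (mucosal height / mucosa length) is non-positive."""


class InsufficientDataError(DabquantError, ValueError):
    """Too few observations or groups for the requested statistic."""


class UndefinedCorrelationError(DabquantError, ValueError):
    """Correlation requested on data with zero variance or mismatched length."""


class PipelineError(DabquantError, RuntimeError):
    """A run-level failure of the analysis pipeline (e.g. no usable samples)."""
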