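"""Exception hierarchy for vertmech."""


class VertmechError(Exception):
    """Base class for all vertmech errors."""


class CurveFormatError(VertmechError):
    """A curve file could not be parsed."""


class CurveValidationError(VertmechError):
    """A curve violates a structural invariant (length, monotonicity, force range)."""


class ExtractionError(VertmechError):
    """A mechanical parameter could not be extracted from a curve."""


class GenerationError(VertmechError):
    """Synthetic curve or cohort generation failed (inconsistent parameters)."""


class StatisticsError(VertmechError):
    """A group-level statistic could not be computed."""
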