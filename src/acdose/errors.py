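"""Exception hierarchy for the acdose pipeline.

Every stage raises a subclass of :class:`AcdoseError` so callers can
distinguish bad inputs from genuine computation failures.
"""


class AcdoseError(Exception):
    """Base class for all acdose errors."""


class InvalidInputError(AcdoseError, ValueError):
    """An argument violates a precondition (negative half-life, bad fraction...)."""


class ConfigurationError(AcdoseError):
    """Inconsistent configuration, e.g. mismatched energy windows or units."""


class SegmentationError(AcdoseError):
    """A VOI operation produced or received an empty mask."""


class DegenerateChainError(AcdoseError):
    """Decay-chain rate ordering makes the requested quantity undefined."""


class NonDecayingTACError(AcdoseError):
    """A two-point time-activity curve increases with time; the effective
    half-life would be negative."""


class NonPhysicalKineticsError(AcdoseError):
    """Effective half-life is not shorter than the physical one, implying
    non-positive biological clearance."""


class InsufficientDataError(AcdoseError):
    """Too few data points for the requested fit."""


class UndefinedRatioError(AcdoseError):
    """A ratio with a zero denominator was requested."""


class PairingError(AcdoseError):
    """Cohort summary received unpaired per-patient data."""


class GeometryError(AcdoseError):
    """Synthetic phantom geometry is inconsistent (e.g. overlapping organs)."""


class ManifestError(AcdoseError):
    """Referenced input files are missing.

    Carries the list of absent paths in ``missing``.
    """

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing input files: {', '.join(map(str, self.missing))}")


class StageError(AcdoseError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
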