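"""Typed failure modes of the estimation pipeline.

Every stage that can fail in a way a caller must handle raises one of
these, so the pipeline can attribute a failure to a stage and report it
instead of emitting a silent zero estimate.
"""


class CarbPlateError(Exception):
    """Base class for all package errors."""


class InvalidSceneError(CarbPlateError):
    """A synthetic scene violates its invariants (overlap, out-of-plate item...)."""


class PlateNotFoundError(CarbPlateError):
    """No elliptical plate border with sufficient edge consensus."""


class InvalidSeedError(CarbPlateError):
    """A segmentation seed falls outside the plate interior."""


class TooSmallRegionError(CarbPlateError):
    """A region has too few pixels for stable feature extraction."""


class InsufficientTextureError(CarbPlateError):
    """Fewer keypoint matches than the two-view geometry needs."""


class PoseFailureError(CarbPlateError):
    """Relative-pose estimation failed (degenerate geometry or no consensus)."""


class NoReferenceError(CarbPlateError):
    """The reference card could not be located; absolute scale is undefined."""


class InsufficientPlatePointsError(CarbPlateError):
    """Too few reconstructed points on the bare plate to fit the plate plane."""


class ReconstructionError(CarbPlateError):
    """Dense reconstruction or volume integration failed."""


class SchemaError(CarbPlateError):
    """A nutrient-density table or study table violates its schema."""
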