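"""Exception hierarchy for the bodyscan pipeline.

Every stage raises a subclass of :class:`BodyScanError` so that the pipeline
runner can attach stage names while letting callers catch one base type.
"""


class BodyScanError(Exception):
    """Base class for all bodyscan errors."""


class InvalidSpecError(BodyScanError, ValueError):
    """A phantom or configuration specification is malformed."""


class EmptyRenderError(BodyScanError):
    """The phantom is outside both camera frusta; nothing was rendered."""


class DepthRangeError(BodyScanError, ValueError):
    """A depth value exceeds the 16-bit millimetre range (65535 mm)."""


class NoBodyFoundError(BodyScanError):
    """IR segmentation found no pixel above the threshold."""


class BadSeedError(BodyScanError, ValueError):
    """The region-growth seed point falls outside the thresholded foreground."""


class EmptyMaskError(BodyScanError):
    """Morphological cleaning removed every foreground pixel."""


class MaskShapeError(BodyScanError, ValueError):
    """Mask and depth frame dimensions disagree."""


class EmptyCloudError(BodyScanError):
    """A masked depth image contains no valid pixel to back-project."""


class RegistrationFailureError(BodyScanError):
    """ICP could not establish overlap between the two views."""


class ReconstructionError(BodyScanError):
    """Surface reconstruction failed (degenerate or rank-deficient cloud)."""


class NonWatertightError(BodyScanError):
    """Mesh cleaning could not reach a watertight surface."""


class VolumeUndefinedError(BodyScanError):
    """Enclosed volume is undefined (open mesh or inconsistent winding)."""


class ReplicateError(BodyScanError):
    """Replicate selection needs a third measurement that was not supplied."""


class DomainError(BodyScanError, ValueError):
    """A physiological or mathematical domain constraint is violated."""


class SingularFitError(BodyScanError):
    """Calibration regression is singular (constant predictor)."""


class InputError(BodyScanError, ValueError):
    """Statistical input is malformed (length mismatch, too few samples)."""


class UndefinedStatisticError(BodyScanError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class StageError(BodyScanError):
    """Wraps an error from a pipeline stage with stage name and input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        self.stage = stage
        self.input_id = input_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed on '{input_id}': {cause}")
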