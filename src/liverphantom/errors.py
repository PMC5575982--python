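"""Exception hierarchy for the phantom pipeline."""


class PhantomError(Exception):
    """Base class for all phantom errors."""


class InvalidConfigError(PhantomError):
    """A configuration value is missing, malformed or out of range."""


class InvalidArgumentError(PhantomError, ValueError):
    """A direct argument violates an operation precondition."""


class CalibrationError(PhantomError):
    """Volume calibration could not reach the target within the grid."""


class PlacementError(PhantomError):
    """Tumor placement violates the interior-margin constraint."""


class RescaleError(PhantomError):
    """Mean rescaling is impossible (non-positive masked mean)."""


class MappingError(PhantomError):
    """Deformable texture mapping diverged (Dice below the floor)."""


class InversionError(PhantomError):
    """Displacement-field inversion did not reach the residual tolerance."""

    def __init__(self, message: str, residual_mm: float | None = None):
        super().__init__(message)
        self.residual_mm = residual_mm


class SegmentationError(PhantomError):
    """Tumor segmentation returned an empty mask."""


class IOFormatError(PhantomError):
    """Unknown file extension or malformed image header."""


class RegistrationWarning(UserWarning):
    """Demons registration finished below the quality bar."""
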