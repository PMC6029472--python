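"""Exception hierarchy for the tnrpet pipeline."""


class TNRError(Exception):
    """Base class for all tnrpet errors."""


class InvalidMetadataError(TNRError, ValueError):
    """Acquisition metadata (injected dose, body weight) is unusable."""


class VolumeIOError(TNRError, OSError):
    """A volume or mask could not be read or written."""


class EmptyRegionError(TNRError, ValueError):
    """An operation received an empty volume of interest."""


class NoLesionError(TNRError, ValueError):
    """No voxel anywhere in the volume reaches the segmentation threshold."""


class SeedMismatchError(TNRError, ValueError):
    """The operator point is too far from any supra-threshold voxel."""


class DegenerateLesionError(TNRError, ValueError):
    """The lesion has zero intensity range, so redigitization is undefined."""


class UndefinedRatioError(TNRError, ArithmeticError):
    """Necrotic core metabolism is zero; the ratio is undefined.

    Carries the partial result so the intermediates remain auditable.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class InvalidSpecError(TNRError, ValueError):
    """A phantom specification is geometrically or physically impossible."""


class DataIntegrityError(TNRError, RuntimeError):
    """The packaged cohort fixture does not match its recorded checksum."""
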