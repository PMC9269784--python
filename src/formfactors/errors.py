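"""Exception types shared across the pipeline stages."""


class FormFactorsError(Exception):
    """Base class for all package errors."""


class MaskFormatError(FormFactorsError):
    """The file could not be read in the requested mask format."""


class DimensionalityError(FormFactorsError):
    """The volume is not a 3D scalar grid."""


class MetadataError(FormFactorsError):
    """Voxel spacing is missing, zero, negative or non-finite."""


class EmptyROIError(FormFactorsError):
    """The mask contains no foreground voxels."""


class DomainError(FormFactorsError, ValueError):
    """An operation was called outside its mathematical domain."""


class CalibrationError(FormFactorsError, ValueError):
    """Requested distribution moments are infeasible."""


class ConfigurationError(FormFactorsError):
    """A pipeline run configuration is incomplete or inconsistent."""
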