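"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`BcrRadiomicsError` so callers can
catch pipeline failures without masking programming errors.
"""


class BcrRadiomicsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BcrRadiomicsError):
    """A file could not be parsed as the expected volumetric format."""


class ValidationError(BcrRadiomicsError):
    """Input data violates a structural invariant (NaN voxels, bad spacing...)."""


class GridMismatchError(BcrRadiomicsError):
    """Image and mask do not share the same voxel grid."""


class EmptyROIError(BcrRadiomicsError):
    """A region of interest contains no foreground voxels."""


class ConfigError(BcrRadiomicsError):
    """An unsupported configuration value was requested."""


class MissingDataError(BcrRadiomicsError):
    """A clinical record lacks a field required by the computation."""


class UndefinedFeatureError(BcrRadiomicsError):
    """A feature is mathematically undefined for the given input."""


class DegenerateLabelsError(BcrRadiomicsError):
    """Only one outcome class is present where both are required."""


class SchemaError(BcrRadiomicsError):
    """A table or model does not match the expected column schema."""


class UnseenBatchError(BcrRadiomicsError):
    """A batch label was not part of the fitted harmonization model."""


class SpecError(BcrRadiomicsError):
    """A synthetic-data specification is internally inconsistent."""
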