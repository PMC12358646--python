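"""Exception hierarchy.

``ValidationError`` covers bad user input (CLI exit code 2);
``InternalConsistencyError`` covers violated internal invariants (exit code 3).
"""


class RobustnessError(Exception):
    """Base class for all package errors."""


class ValidationError(RobustnessError):
    """Invalid input data, parameters, or file contents."""


class NotAVolumeError(ValidationError):
    """File payload is not a 3-D scalar volume."""


class NonPositiveSpacingError(ValidationError):
    """Voxel spacing must be strictly positive on every axis."""


class NonFiniteDoseError(ValidationError):
    """Dose values must be finite (no NaN/Inf)."""


class NegativeDoseError(ValidationError):
    """Dose values must be non-negative."""


class UnsupportedFormatError(ValidationError):
    """File format or DICOM transfer syntax not supported."""


class LatticeMismatchError(ValidationError):
    """Grids/masks do not share one lattice (shape, spacing, origin)."""


class EmptyROIError(ValidationError):
    """ROI mask selects no voxels."""


class ScenarioCountError(ValidationError):
    """A scenario set must contain exactly 12 uncertainty scenarios."""


class DuplicateScenarioError(ValidationError):
    """Scenario ids must be unique."""


class MissingScenarioError(ValidationError):
    """A required scenario is absent from a manifest or set."""


class MetricParameterError(ValidationError):
    """Metric parameter out of range (e.g. absolute volume > ROI volume)."""


class DegenerateGeometryError(ValidationError):
    """Phantom geometry rasterizes to no voxels or leaves the grid."""


class InternalConsistencyError(RobustnessError):
    """A computed result violated a structural invariant."""
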