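"""Exception hierarchy for hybridir.

All package-specific failures derive from :class:`HybridIRError` so callers
can catch one base class at tool boundaries (CLI, experiment harness).
"""


class HybridIRError(Exception):
    """Base class for all hybridir errors."""


class VolumeFormatError(HybridIRError):
    """A volume file could not be read or has an unsupported format."""


class GeometryError(HybridIRError):
    """Image geometries are invalid or incompatible (direction, grid mismatch)."""


class DomainError(HybridIRError):
    """A point lies outside the supported region of a transform."""


class ParameterError(HybridIRError):
    """An operation was called with invalid parameters."""


class ConfigurationError(HybridIRError):
    """A registration/experiment configuration is inconsistent."""


class DegenerateOverlapError(HybridIRError):
    """No fixed voxel maps inside the moving image domain."""


class SpecificationError(HybridIRError):
    """A phantom specification describes an impossible geometry."""


class ConvergenceError(HybridIRError):
    """An iterative calibration failed to reach its target."""
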