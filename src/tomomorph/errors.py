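"""Exception hierarchy.

Validation errors (bad inputs, bad config) are distinguished from
computation errors (a stage that failed on valid inputs) so the CLI can
map them to different exit codes.
"""


class TomomorphError(Exception):
    """Base class for all package errors."""


class ValidationError(TomomorphError):
    """Input data or configuration violates a documented precondition."""


class FormatError(ValidationError):
    """A file could not be parsed in its declared format."""


class UnitError(ValidationError):
    """Missing or inconsistent physical units (e.g. voxel size)."""


class ConfigurationError(ValidationError):
    """Run configuration is internally inconsistent."""


class ComputationError(TomomorphError):
    """A stage failed on formally valid inputs."""


class EstimationError(ComputationError):
    """A statistical estimate could not be formed."""


class PlacementError(ComputationError):
    """Rigid-motion placement could not satisfy its constraints."""
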