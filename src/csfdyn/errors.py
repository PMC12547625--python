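"""Exception hierarchy shared by all csfdyn modules.

Every error raised by the library derives from :class:`CsfDynError`, so CLI
and pipeline callers can catch one base class.  The subclasses map onto the
CLI exit codes: file/format problems (exit 2), validation/configuration
problems (exit 3), and computation/QC failures (exit 4).
"""


class CsfDynError(Exception):
    """Base class for all csfdyn errors."""


class FormatError(CsfDynError):
    """Input file does not conform to the expected on-disk format."""


class ValidationError(CsfDynError):
    """Input values violate a documented precondition or invariant."""


class ConfigError(ValidationError):
    """Run configuration (YAML/flags) is malformed or inconsistent."""


class ParameterError(ValidationError):
    """A numeric parameter is outside its admissible range."""


class InsufficientDataError(CsfDynError):
    """Not enough samples/volumes/voxels to perform the operation."""


class MaskError(CsfDynError):
    """A required mask is empty or incompatible with the data grid."""


class PlacementError(CsfDynError):
    """An ROI (at some candidate displacement) does not fit inside the grid."""


class ComputationError(CsfDynError):
    """A numerical stage failed (rank-deficient design, empty ROI, ...)."""


class QcError(CsfDynError):
    """A per-scan quality-control rule failed (e.g. too few CSF voxels)."""
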