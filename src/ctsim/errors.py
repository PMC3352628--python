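"""Exception hierarchy for ctsim.

Every named failure mode in the library raises a distinct subclass of
:class:`CTSimError` so callers (and the CLI) can map errors to exit codes
without string matching.
"""


class CTSimError(Exception):
    """Base class for all ctsim domain errors."""


class InvalidParameterError(CTSimError, ValueError):
    """A parameter violates its documented precondition."""


class VolumeFormatError(CTSimError):
    """A volume file is missing, corrupt, or in an unsupported layout."""


class InconsistentSpacingError(VolumeFormatError):
    """A DICOM series has non-uniform slice spacing (e.g. a missing slice)."""


class NoObjectError(CTSimError):
    """An operation that needs at least one object pixel got an empty mask."""


class DegenerateContourError(CTSimError):
    """A contour is too small or has zero area for the requested operation."""


class OutOfBoundsError(CTSimError, IndexError):
    """A seed point or contour lies outside the volume grid."""
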