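"""Exception hierarchy for the sinus-superimposition pipeline.

``SinusidError`` is the common base so callers can catch pipeline failures
without masking programming errors; CLI maps these to exit code 1 and
usage problems to exit code 2.
"""


class SinusidError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(SinusidError, ValueError):
    """A configuration value violates its invariant."""


class SeedRejectionError(SinusidError, ValueError):
    """A region-growing seed lies outside the requested gray range."""


class EmptySegmentationError(SinusidError, ValueError):
    """Surface extraction was asked to mesh an empty mask."""


class OpenSurfaceError(SinusidError, ValueError):
    """The mask touches the grid boundary, so the iso-surface cannot close."""


class ResolutionError(SinusidError, ValueError):
    """Voxel spacing too coarse to resolve the shape being voxelized."""


class DegenerateGeometryError(SinusidError, ValueError):
    """Point configuration too degenerate for rigid alignment."""


class EmptyInputError(SinusidError, ValueError):
    """An operation received an empty mesh or distance field."""


class FormatError(SinusidError, ValueError):
    """A file could not be parsed in the expected format."""
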