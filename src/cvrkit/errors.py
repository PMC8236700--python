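"""Exception hierarchy for cvrkit."""


class CvrkitError(Exception):
    """Base class for all cvrkit errors."""


class ProtocolError(CvrkitError, ValueError):
    """Invalid stimulus protocol specification."""


class CoverageError(CvrkitError, ValueError):
    """Stimulus trace does not cover the BOLD acquisition window."""


class AlignmentError(CvrkitError, ValueError):
    """Temporal alignment is undefined (e.g. zero-variance input)."""


class FitError(CvrkitError, ValueError):
    """Degenerate voxel-wise regression (e.g. constant regressor)."""


class GeometryError(CvrkitError, ValueError):
    """Incompatible or unsupported voxel grid geometry."""
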