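"""Exception hierarchy for the pipeline."""


class WbidError(Exception):
    """Base class for package errors."""


class BvhParseError(WbidError):
    """Malformed BVH file; message names the offending line."""


class MappingError(WbidError):
    """Motion skeleton cannot be mapped onto the 15-segment model."""


class SchemaError(WbidError):
    """A delimited table is missing required columns."""


class DataQualityError(WbidError):
    """Dropout gap longer than the configured tolerance."""


class FormatError(WbidError):
    """Structural defect in a force-plate record."""


class AlignmentError(WbidError):
    """Cross-correlation peak below the acceptance threshold."""


class ParameterError(WbidError):
    """Invalid processing parameter (e.g. cutoff above Nyquist)."""


class CoverageError(WbidError):
    """A segment has neither sensor data nor derivable kinematics."""


class SolverError(WbidError):
    """The force-decomposition solver failed at a frame."""
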