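"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code so shell callers can
distinguish bad inputs from bad geometry from failed statistics.
"""


class DynfetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(DynfetError):
    """Malformed or inconsistent user input (tables, configs, records)."""

    exit_code = 2


class CalibrationError(DynfetError):
    """Missing or inconsistent SUV calibration metadata."""

    exit_code = 3


class GridMismatchError(DynfetError):
    """Image and mask are not defined on the same voxel grid."""

    exit_code = 4


class GeometryError(DynfetError):
    """A ROI/VOI or phantom geometry request cannot be satisfied."""

    exit_code = 5


class AnalysisError(DynfetError):
    """A statistical stage cannot run (degenerate classes, no events, ...)."""

    exit_code = 6


class StageError(DynfetError):
    """Wraps an error raised inside a named pipeline stage."""

    exit_code = 7

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
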