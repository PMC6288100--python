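"""Exception hierarchy for the shearfret pipeline."""


class ShearFretError(Exception):
    """Base class for all package errors."""


class ValidationError(ShearFretError, ValueError):
    """Invalid parameter or data contract violation."""


class ShapeError(ValidationError):
    """Mismatched array/stack shapes between channels or frames."""


class NoCellFoundError(ShearFretError, RuntimeError):
    """Segmentation produced no component of sufficient area."""


class DegenerateGeometryError(ShearFretError, RuntimeError):
    """Mask extent along the flow axis too small to bin."""


class StageError(ShearFretError, RuntimeError):
    """Pipeline stage failure, annotated with stage name and frame index."""

    def __init__(self, stage: str, frame_index: int | None, cause: BaseException):
        self.stage = stage
        self.frame_index = frame_index
        self.cause = cause
        where = f"stage '{stage}'"
        if frame_index is not None:
            where += f", frame {frame_index}"
        super().__init__(f"{where}: {cause}")
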