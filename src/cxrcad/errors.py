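"""Exception hierarchy for the cxrcad pipeline."""


class CxrcadError(Exception):
    """Base class for all cxrcad errors."""


class FormatError(CxrcadError):
    """A file does not match the expected on-disk format."""


class ValidationError(CxrcadError):
    """Input data violates a contract (bad labels, duplicate ids, ...)."""


class GeometryError(CxrcadError):
    """Patch/grid geometry is inconsistent with the image dimensions."""


class PlacementError(CxrcadError):
    """A requested nodule position falls outside the lung field."""


class InsufficientDataError(CxrcadError):
    """A statistical test was asked to run on too few samples."""


class AggregationError(CxrcadError):
    """Image-level aggregation received no patch predictions."""


class StageError(CxrcadError):
    """A pipeline stage failed; carries the stage name and offending item."""

    def __init__(self, stage: str, item: str, cause: Exception):
        self.stage = stage
        self.item = item
        self.cause = cause
        super().__init__(f"stage {stage!r} failed on {item!r}: {cause}")
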