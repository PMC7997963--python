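"""Exception hierarchy for cellsig."""


class CellSigError(Exception):
    """Base class for all cellsig errors."""


class ConfigError(CellSigError, ValueError):
    """Invalid configuration (bad threshold, unknown gene, missing field)."""


class FormatError(CellSigError, ValueError):
    """Malformed input file (MTX triplet, GMT, metadata table)."""


class EmptyResultError(CellSigError, ValueError):
    """An operation would return an empty object (e.g. QC removed all cells)."""


class PipelineStageError(CellSigError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
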