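"""Exception hierarchy shared across the pipeline stages."""


class PPRChipError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PPRChipError):
    """Malformed input file or record (duplicate labels, bad columns, ...)."""


class CoordinateError(PPRChipError):
    """A genomic or protein coordinate outside the valid range."""


class AnnotationError(PPRChipError):
    """A motif annotation that cannot support the requested operation."""


class AlphabetError(PPRChipError):
    """A residue or base outside the allowed alphabet."""


class UsageError(PPRChipError):
    """An argument outside its documented range."""


class StageError(PPRChipError):
    """A pipeline stage failed; carries the stage name for CLI reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
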