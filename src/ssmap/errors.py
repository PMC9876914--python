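"""Exception hierarchy shared across the pipeline stages."""


class SsmapError(Exception):
    """Base class for all package errors."""


class InputError(SsmapError):
    """Invalid user input or parameter (CLI exit code 2)."""


class FormatError(InputError):
    """A file does not conform to the expected format."""


class DataIntegrityError(SsmapError):
    """Inputs contradict each other (e.g. reference base mismatch)."""


class SelectionError(SsmapError):
    """No plant qualifies for the phenotype-selected pool."""


class UndefinedIndexError(SsmapError):
    """SNP index requested at a site with zero read depth."""


class StageError(SsmapError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
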