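"""Exception hierarchy shared across the pipeline."""


class RhizonetError(Exception):
    """Base class for all package errors."""


class FormatError(RhizonetError):
    """A file violates the structural expectations of its format (e.g. duplicate ids)."""


class ParseError(RhizonetError):
    """A file could not be tokenised (ragged rows, undecodable content)."""


class SchemaError(RhizonetError):
    """A table is missing required columns or is empty."""


class ValidationError(RhizonetError):
    """Values violate domain constraints (negative counts, densities, ...)."""


class ParameterError(RhizonetError, ValueError):
    """A function argument is outside its admissible range."""


class InputError(RhizonetError, ValueError):
    """Input data cannot support the requested computation."""


class GenerationError(RhizonetError):
    """The synthetic-community configuration is statistically infeasible."""


class DegenerateModuleError(RhizonetError):
    """A module is too small for the requested decomposition."""


class StageError(RhizonetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
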