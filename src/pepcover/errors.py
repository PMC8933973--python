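"""Exception hierarchy shared across the pipeline."""


class PepcoverError(Exception):
    """Base class for all pipeline errors."""


class FastaParseError(PepcoverError):
    """Raised for malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DuplicateIdError(PepcoverError):
    """Two records share a protein identifier within one community."""


class SchemaError(PepcoverError):
    """A tabular input is missing required columns or violates a field grammar."""


class EmptyTargetError(PepcoverError):
    """A requested family has no annotated member proteins."""


class EmptyPeptidomeError(PepcoverError):
    """Digestion produced no peptides (e.g. every protein shorter than the trim)."""


class InstanceTooLargeError(PepcoverError):
    """Exhaustive cover search refused: instance exceeds the stated size bound."""


class SpecValidationError(PepcoverError):
    """A synthetic community specification is internally inconsistent."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        if field is not None:
            message = f"{field}: {message}"
        super().__init__(message)
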