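"""Exception hierarchy shared across hybnet modules."""


class HybnetError(Exception):
    """Base class for all hybnet errors."""


class ParseError(HybnetError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(HybnetError):
    """A dataset or parameter violates a structural invariant."""


class SchemaError(ValidationError):
    """A tabular input does not match the documented column layout."""


class MissingGenotypeError(HybnetError):
    """A per-locus operation was asked to consume a missing genotype."""


class DistanceUndefinedError(HybnetError):
    """A pair of individuals shares no comparable (jointly typed) locus."""


class ConfigurationError(HybnetError):
    """A simulation or pipeline configuration is unusable."""
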