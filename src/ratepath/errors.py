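"""Exception hierarchy for ratepath."""


class RatepathError(Exception):
    """Base class for all ratepath errors."""


class SchemaError(RatepathError):
    """A structured input file violates the documented schema."""


class ValidationError(RatepathError):
    """An in-memory record violates a physical or structural invariant."""


class ParseError(RatepathError):
    """A text artifact (log file, IRC table, *.eif) could not be parsed."""


class NumericalError(RatepathError):
    """A numerical procedure failed to converge or lost accuracy."""
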