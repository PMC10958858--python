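"""Exception hierarchy used across the pipeline."""


class MethageError(Exception):
    """Base class for all package errors."""


class ParseError(MethageError):
    """A file could not be parsed; the message names the file and line."""


class ValidationError(MethageError):
    """An argument or configuration violates a documented invariant."""


class DataError(MethageError):
    """The data are structurally valid but unusable for the requested step."""
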