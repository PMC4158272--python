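"""Exception types shared across the package."""


class ChemtriageError(Exception):
    """Base class for all package errors."""


class ValidationError(ChemtriageError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ChemtriageError, ValueError):
    """A file could not be parsed in the declared format."""


class ModelFormatError(ChemtriageError, ValueError):
    """A model file is corrupted or has an unsupported format version."""
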