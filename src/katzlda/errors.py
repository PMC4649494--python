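"""Exception hierarchy shared by all modules."""


class KatzldaError(Exception):
    """Base class for all package errors."""


class InputError(KatzldaError):
    """Empty or unusable input file."""


class TableParseError(KatzldaError):
    """Malformed row in a tabular input; message names the offending line."""


class EntityNotFoundError(KatzldaError, KeyError):
    """An identifier was not found on the requested side or corpus."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain message
        return Exception.__str__(self)


class StructuralError(KatzldaError):
    """Dimension mismatch, id-order mismatch, or a cyclic ontology."""


class ConfigurationError(KatzldaError):
    """Parameter combination under which the requested quantity is undefined."""


class NumericError(KatzldaError):
    """Non-finite values or a violated spectral condition."""
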