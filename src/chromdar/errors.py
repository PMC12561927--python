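"""Exception hierarchy shared across the package."""


class ChromdarError(Exception):
    """Base class for all package errors."""


class ParseError(ChromdarError):
    """A file could not be parsed (malformed line, missing column)."""


class ValidationError(ChromdarError):
    """Input violates a documented contract (bad coordinates, negative counts)."""


class ConfigurationError(ChromdarError):
    """Invalid configuration value or unknown option."""


class MissingInputError(ChromdarError):
    """A pipeline stage was requested without its required input."""
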