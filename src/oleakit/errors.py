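"""Exception hierarchy shared across the toolkit."""


class OleakitError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(OleakitError):
    """A required column or field is absent or mislabelled."""


class ValidationError(OleakitError):
    """Data violate a container invariant (duplicate IDs, negative %, ...)."""


class ParseError(OleakitError):
    """A cell could not be interpreted; message carries its location."""


class DegenerateInputError(OleakitError):
    """Input is structurally valid but the requested statistic is undefined."""
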