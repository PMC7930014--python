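"""Exception types shared across the pipeline."""


class RovannotError(Exception):
    """Base class for all package errors."""


class ValidationError(RovannotError, ValueError):
    """An input value violates a documented precondition."""


class FormatError(RovannotError, ValueError):
    """A file does not conform to its declared schema."""


class ReferentialError(RovannotError, ValueError):
    """A record references a key that does not resolve."""


class SchemaMismatchError(RovannotError, RuntimeError):
    """An existing database file carries an incompatible schema."""
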