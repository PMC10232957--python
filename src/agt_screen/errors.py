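"""Exception types shared across the package."""


class AgtScreenError(Exception):
    """Base class for package errors."""


class SchemaError(AgtScreenError):
    """A file is missing required columns or has an unusable layout."""


class ValidationError(AgtScreenError):
    """Data violate a structural or range invariant."""


class DesignError(AgtScreenError):
    """The experimental design cannot support the requested analysis."""
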