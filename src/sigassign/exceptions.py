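"""Exception hierarchy shared across the package."""


class SigAssignError(Exception):
    """Base class for all package errors."""


class ValidationError(SigAssignError, ValueError):
    """Raised when input data violates a documented contract."""


class SchemaError(ValidationError):
    """Raised when channel labels do not match any known mutational schema."""
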