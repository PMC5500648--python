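"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a structural contract.

    Carries a human-readable message that names the offending file,
    coordinate, subject or row so failures are actionable.
    """


class InvalidParameterError(ValueError):
    """Raised when a caller-supplied parameter is out of its valid range."""
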