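"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when user-supplied inputs violate a documented precondition."""


class FitError(RuntimeError):
    """Raised when an internal numerical assumption is violated (not a user error)."""
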