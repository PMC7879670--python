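"""Exception hierarchy."""


class GeffError(Exception):
    """Base class for all package errors."""


class ValidationError(GeffError):
    """Raised when an input violates a documented precondition."""
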