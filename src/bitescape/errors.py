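"""Exception types shared across the package."""


class BitescapeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BitescapeError, ValueError):
    """An input violates a documented contract (shapes, enums, signs)."""


class FormatError(BitescapeError, ValueError):
    """A file does not match the documented on-disk layout."""


class DegenerateWindowError(BitescapeError, ValueError):
    """A strike window cannot be detected (e.g. stationary track)."""


class FitError(BitescapeError, RuntimeError):
    """A statistical fit failed to converge or is unidentifiable."""
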