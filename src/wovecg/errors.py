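"""Exception types shared across the package."""


class WovecgError(Exception):
    """Base class for package-specific failures."""


class DegenerateModelError(WovecgError):
    """A transfer function has a pole at (or numerically on top of) an
    evaluation frequency, so its response there is meaningless."""


class SingularInversionError(WovecgError):
    """Unregularized spectral division was requested where the transfer
    function magnitude vanishes but the signal carries energy."""


class EmptyResultError(WovecgError):
    """An operation that must yield at least one element yielded none
    (e.g. beat averaging with no beat fully inside the record)."""
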