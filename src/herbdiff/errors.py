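"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/format problems exit 2,
numerical failures exit 3.
"""


class HerbdiffError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HerbdiffError):
    """A file or string does not conform to the expected format."""


class ValidationError(HerbdiffError):
    """Input values violate a documented precondition or invariant."""


class NumericalError(HerbdiffError):
    """A computation degenerated (rank deficiency, zero norm, ...)."""
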