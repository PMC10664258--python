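"""Exception hierarchy shared across the package."""


class AtacsimError(Exception):
    """Base class for all package errors."""


class ParseError(AtacsimError):
    """A text input could not be parsed; the message names the offending line."""


class ValidationError(AtacsimError):
    """An object violates one of its structural invariants."""


class LayoutMismatchError(ValidationError):
    """Two objects that must share a genome layout or bin grid do not."""


class UndefinedStatisticError(AtacsimError):
    """A statistic is mathematically undefined on the given input.

    Raised instead of returning NaN: a silent NaN propagated into an
    area-under-curve integration would corrupt downstream summaries.
    """
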