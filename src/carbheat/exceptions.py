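"""Exception hierarchy for carbheat."""


class CarbheatError(Exception):
    """Base class for all carbheat errors."""


class ValidationError(CarbheatError, ValueError):
    """An input violates a physical or schema invariant."""


class InsufficientDataError(CarbheatError, ValueError):
    """Too few observations for the requested statistical operation."""


class DegenerateSampleError(CarbheatError, ValueError):
    """A sample has no carbohydrate mass (or an all-zero composition)."""
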