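"""Exception hierarchy for mrgxe."""


class MRGxEError(Exception):
    """Base class for all mrgxe errors."""


class InputError(MRGxEError, ValueError):
    """Malformed, insufficient, or degenerate user input (bad columns,
    too few observations, constant variables in roles that require
    variation, mismatched lengths)."""


class IdentificationError(MRGxEError):
    """The requested model is not identified from the data supplied:
    a degenerate instrument, a rank-deficient design, or a vanishing
    denominator in a ratio estimand."""
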