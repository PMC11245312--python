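"""Exception hierarchy.

All statemix-specific failures derive from :class:`StatemixError` so callers
(and the CLI) can catch one base class.
"""


class StatemixError(Exception):
    """Base class for all statemix errors."""


class FormatError(StatemixError):
    """Malformed or inconsistent input file."""


class InputError(StatemixError):
    """Invalid in-memory input (shapes, signs, empty intersections)."""


class LabelingError(StatemixError):
    """Inconsistent cell-state / cell-type label pairing."""


class DegenerateStateError(StatemixError):
    """A cell state with no counts and no pseudocount to rescue it."""


class ParameterError(StatemixError):
    """A parameter outside its documented range."""
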