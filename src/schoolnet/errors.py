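"""Exception hierarchy for schoolnet.

Every failure mode the analysis contracts define maps to one concrete
exception class, all rooted at :class:`SchoolnetError` so callers can
catch the whole family at pipeline level.
"""


class SchoolnetError(Exception):
    """Base class for all schoolnet errors."""


class MalformedInputError(SchoolnetError):
    """Input file violates the tabular trajectory contract."""


class DegeneratePointError(SchoolnetError):
    """A position coincides with the tank center; its angle is undefined."""


class UndefinedHeadingError(SchoolnetError):
    """A track never exceeds the speed floor, so no heading can be assigned."""


class TooShortError(SchoolnetError):
    """A series is too short for the requested window or recursion."""


class UnboundedTurnError(SchoolnetError):
    """No threshold crossing bounds an individual U-turn within the record."""


class IncompleteEventError(SchoolnetError):
    """A collective U-turn is missing a matched individual turn for some fish."""


class ZeroDurationError(SchoolnetError):
    """Normalized time is undefined for a zero-duration event."""


class InsufficientPoolError(SchoolnetError):
    """The bootstrap pool has fewer source events than the group size."""


class InvalidGraphError(SchoolnetError):
    """The influence graph of the simulator is ill-formed."""


class UndefinedSimilarityError(SchoolnetError):
    """Cosine similarity is undefined for a zero-norm summary vector."""
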