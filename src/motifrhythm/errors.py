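"""Exception hierarchy for the motifrhythm pipeline.

Exit-code mapping used by the CLI: ValidationError -> 2,
InsufficientDataError -> 3.
"""


class MotifRhythmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MotifRhythmError):
    """Input violates a structural invariant (non-monotone onsets,
    overlapping intervals, malformed config, ...)."""


class InsufficientDataError(MotifRhythmError):
    """A computation was requested on fewer observations than it needs
    (e.g. CV or nPVI on a single interval, a correlation on < 3 points)."""


class TierNotFoundError(ValidationError):
    """The requested interval tier is absent from a TextGrid file."""


class TextGridDialectError(ValidationError):
    """The TextGrid could not be parsed, or a point tier was found where an
    interval tier was expected."""
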