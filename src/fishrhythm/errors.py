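"""Exception hierarchy shared by all fishrhythm modules."""


class FishRhythmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FishRhythmError):
    """An input file does not have the expected structure (e.g. a missing column)."""


class ParseError(FishRhythmError):
    """A value in an input file could not be interpreted (row context included)."""


class ValidationError(FishRhythmError):
    """Data violate a structural invariant (ordering, overlap, sign, range)."""


class InsufficientDataError(FishRhythmError):
    """Too few elements or intervals for the requested statistic."""


class ResolutionError(FishRhythmError):
    """The sampling rate is too coarse to represent distinct onsets."""
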