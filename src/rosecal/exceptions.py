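"""Exception hierarchy.

All package-specific failures derive from :class:`RosecalError` so callers
can catch one base class at workflow boundaries.
"""


class RosecalError(Exception):
    """Base class for all rosecal errors."""


class GridError(RosecalError):
    """Invalid wavenumber grid: duplicates, too short, or mismatched grids."""


class ParseError(RosecalError):
    """Malformed input file (non-numeric cell, bad header, ...)."""


class UnsupportedDialectError(ParseError):
    """JCAMP-DX file uses a dialect outside the minimal supported subset."""


class ExtrapolationError(RosecalError):
    """Requested grid point lies outside the span of the source spectrum."""


class EmptySelectionError(RosecalError):
    """A wavenumber window selects no points of the grid."""


class NormalizationError(RosecalError):
    """Vector normalization of a (near-)constant spectrum."""


class FoldError(RosecalError):
    """A cross-validation fold is degenerate (zero response variance)."""


class ConfigError(RosecalError):
    """Invalid run configuration; the message names the offending key."""
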